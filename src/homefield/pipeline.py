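"""End-to-end orchestration: run the full HFA analysis and write a report.

``run_pipeline`` executes every stage — filtering, home assignment, the
full/control model fits, Type-II variance partitions, yearly HFA with
bootstrap SEs, trend and stability regressions, the within-cell permutation
null, and (when an environmental table is supplied) the site ordination —
then writes TSV tables plus a JSON summary of every scalar.  All artifacts
record the master seed, package version and input digests, and a rerun with
an identical configuration byte-reproduces them.  Results are accumulated
in memory and written only after every stage succeeds, so a failing stage
leaves no partial output behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .model import HomeFieldModel
from .ordination import ordinate_environment, read_env_table
from .permutation import DEFAULT_PROBS, null_summary
from .trials import FilterRules

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one reproducible analysis run."""

    trials_path: str
    out_dir: str
    env_path: str | None = None
    column_map: dict = field(default_factory=dict)
    rules: FilterRules | None = field(default_factory=FilterRules)
    min_cells: int = 1
    n_boot: int = 200
    n_perm: int = 999
    probs: tuple = DEFAULT_PROBS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        missing = object()
        rules = raw.pop("rules", missing)
        cfg = cls(**raw)
        if rules is not missing:  # an explicit null disables filtering
            cfg.rules = FilterRules(**rules) if isinstance(rules, dict) else rules
        return cfg


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; write TSV tables and ``summary.json``.

    Returns the summary dictionary.  Any stage failure raises with the
    stage name; nothing is written unless every stage succeeds.
    """
    trials_path = Path(config.trials_path)
    if not trials_path.exists():
        raise FileNotFoundError(f"input trial file not found: {trials_path}")
    if config.env_path is not None and not Path(config.env_path).exists():
        raise FileNotFoundError(f"environment table not found: {config.env_path}")

    stage = "read/filter"
    outputs: dict[str, object] = {}
    summary: dict = {
        "seed": config.seed,
        "package_version": __version__,
        "inputs": {"trials": {"path": str(trials_path), "sha256": _digest(trials_path)}},
    }
    try:
        model = HomeFieldModel.from_csv(
            trials_path,
            column_map=config.column_map,
            rules=config.rules,
            min_cells=config.min_cells,
        )
        ds = model.dataset
        summary["data"] = {
            "n_records": len(ds),
            "n_varieties": len(ds.varieties),
            "n_sites": len(ds.sites),
            "n_years": len(ds.years),
            "n_site_years": ds.n_cells,
            "mean_yield": float(ds.frame["yield"].mean()),
        }
        outputs["home_map.tsv"] = model.home

        stage = "model fit"
        res = model.fit()
        cmp_ = res.comparison
        share = res.home_share()
        boot_se = res.bootstrap_se(n_boot=config.n_boot, seed=config.seed)
        summary["hfa"] = {
            "estimate": res.hfa,
            "model_se": res.hfa_se,
            "bootstrap_se": boot_se,
            "pct_of_mean_yield": 100 * res.hfa_relative,
        }
        summary["model_comparison"] = {
            "aic_full": cmp_.aic_full,
            "aic_control": cmp_.aic_control,
            "bic_full": cmp_.bic_full,
            "bic_control": cmp_.bic_control,
            "delta_aic": cmp_.delta_aic,
            "delta_bic": cmp_.delta_bic,
        }
        summary["home_share"] = {
            "of_control_residual_pct": 100 * share.of_residual,
            "of_total_pct": 100 * share.of_total,
        }
        coef = pd.DataFrame(
            {"estimate": res.params, "se": res.bse}
        )
        outputs["coefficients.tsv"] = coef

        stage = "variance partition"
        vp = res.variance_partition(include_home=False)
        vph = res.variance_partition(include_home=True)
        outputs["variance_partition.tsv"] = vp
        outputs["variance_partition_with_home.tsv"] = vph
        summary["variance_shares_pct"] = {
            term: 100 * float(s) for term, s in vp.shares.items()
        }

        stage = "yearly HFA"
        yearly = res.yearly_hfa(n_boot=config.n_boot, seed=config.seed)
        outputs["yearly_hfa.tsv"] = yearly
        summary["yearly_hfa"] = {
            str(y): float(v) for y, v in yearly.estimates.items()
        }
        summary["skipped_years"] = yearly.skipped

        stage = "trend regressions"
        from .yearly import trend_regression

        hfa_trend = trend_regression(yearly.estimates)
        yield_trend = res.mean_yield_trend()
        summary["hfa_trend"] = dataclasses.asdict(hfa_trend)
        summary["mean_yield_trend"] = dataclasses.asdict(yield_trend)

        stage = "stability regression"
        stab = res.stability()
        summary["stability"] = {
            "slope": stab.slope,
            "r2": stab.r2,
            "p_slope": stab.p_slope,
            "n_varieties": stab.n_varieties,
        }

        stage = "permutation null"
        nd = res.null_distribution(n_perm=config.n_perm, seed=config.seed)
        ns = null_summary(nd, probs=config.probs, observed=yearly.estimates)
        outputs["null_draws.tsv"] = nd
        outputs["null_summary.tsv"] = ns
        med = ns.quantiles[0.5] if 0.5 in ns.quantiles.columns else None
        null_info = {
            "n_perm": config.n_perm,
            "mean": float(nd.estimates.mean()) if len(nd.draws) else None,
        }
        if med is not None and len(yearly.estimates):
            common = [y for y in yearly.estimates.index if y in med.index]
            below = sum(yearly.estimates[y] <= med[y] for y in common)
            null_info["n_years_observed_le_null_median"] = int(below)
            null_info["n_years_compared"] = len(common)
            if ns.tail is not None:
                null_info["tail_proportion_by_year"] = {
                    str(y): float(v) for y, v in ns.tail.items()
                }
        summary["null"] = null_info

        if config.env_path is not None:
            stage = "environment ordination"
            env = read_env_table(config.env_path)
            summary["inputs"]["environment"] = {
                "path": str(config.env_path),
                "sha256": _digest(config.env_path),
            }
            ord_ = ordinate_environment(env)
            outputs["ordination"] = ord_
            summary["ordination"] = {
                "proportion_of_variance": {
                    c: float(p) for c, p in ord_.proportion.items()
                },
                "cumulative_pc4_pct": 100 * float(ord_.proportion.iloc[:4].sum()),
                "dropped_variables": ord_.dropped,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs["home_map.tsv"].to_tsv(out_dir / "home_map.tsv")
    outputs["coefficients.tsv"].to_csv(out_dir / "coefficients.tsv", sep="\t",
                                       index_label="term")
    outputs["variance_partition.tsv"].to_tsv(out_dir / "variance_partition.tsv")
    outputs["variance_partition_with_home.tsv"].to_tsv(
        out_dir / "variance_partition_with_home.tsv"
    )
    outputs["yearly_hfa.tsv"].to_tsv(out_dir / "yearly_hfa.tsv")
    outputs["null_draws.tsv"].to_tsv(out_dir / "null_draws.tsv")
    outputs["null_summary.tsv"].to_tsv(out_dir / "null_summary.tsv")
    if "ordination" in outputs:
        outputs["ordination"].to_tsv(
            out_dir / "ordination_scores.tsv", out_dir / "ordination_loadings.tsv"
        )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; outputs in %s", out_dir)
    return summary
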