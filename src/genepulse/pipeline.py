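"""End-to-end runs: data (ingested or simulated) -> inequality -> matched
excess -> rate model, with a manifest recording seeds, filter accounting and
output checksums, and a one-page report renderer."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .excess import DEFAULT_COVARIATES, MatchedExcessModel
from .inequality import era_report, era_split, publication_ranks
from .ingest import ingest_bundle
from .ratemodel import PublicationRateModel, SeparationError, hot_logistic
from .simulate import (
    SimulationConfig,
    classes_from_shocks,
    generate_association_table,
    inject_gwas_shocks,
    sample_shocks,
    simulate_histories,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one of ``inputs`` (paths for ingestion) or ``simulation`` (a
    :class:`SimulationConfig` mapping, optionally with a ``shocks`` schedule)
    must be set.
    """

    inputs: dict | None = None
    simulation: dict | None = None
    shocks: dict | None = None
    era_cutoff: int = 2005
    window: int = 3
    recent_window: int = 3
    p_max: float | None = None
    or_ci_min: float | None = None
    fit_years: tuple[int, int] = (1950, 2015)
    fit_starts: int = 5
    seed: int = 0
    out_dir: str = "genepulse_run"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("exactly one of inputs/simulation must be configured")
        self.fit_years = tuple(self.fit_years)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Rerunning with the same configuration reproduces every deterministic
    output byte for byte (all randomness flows from ``config.seed``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "genepulse_version": __version__,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()},
            "fit_years": list(config.fit_years),
        },
        "stages": {},
    }

    # -- stage: data -----------------------------------------------------
    if config.simulation is not None:
        sim = SimulationConfig.from_dict({"seed": config.seed, **config.simulation})
        histories = simulate_histories(sim)
        shocks = []
        associations = None
        if config.shocks:
            sh = dict(config.shocks)
            shocks = sample_shocks(
                histories.genes,
                n_shocks=sh["n"],
                t0_range=tuple(sh["t0_range"]),
                boost_start=sh["boost_start"],
                boost_end=sh.get("boost_end"),
                window=sh.get("window", config.window),
                seed=config.seed + 1,
            )
            histories = inject_gwas_shocks(histories, shocks, seed=config.seed + 2)
            associations = generate_association_table(shocks, seed=config.seed + 3)
        classes = classes_from_shocks(histories, shocks, associations)
        manifest["stages"]["data"] = {
            "mode": "simulate",
            "n_genes": int(len(histories.genes)),
            "year_range": list(histories.year_range),
            "n_shocks": len(shocks),
        }
    else:
        res = ingest_bundle(**config.inputs, year_range=config.fit_years)
        histories, classes = res.histories, res.classes
        manifest["stages"]["data"] = {"mode": "ingest", "accounting": res.accounting}

    histories.counts.to_csv(out / "histories.tsv", sep="\t")
    classes.to_csv(out / "classes.tsv", sep="\t")

    # -- stage: inequality -------------------------------------------------
    ineq = era_report(histories, classes, cutoff_year=config.era_cutoff)
    _write_json(ineq, out / "inequality.json")
    pre, post = era_split(histories, config.era_cutoff)
    pd.DataFrame(
        {
            "pre_pubs": pre,
            "post_pubs": post,
            "pre_rank": publication_ranks(pre),
            "post_rank": publication_ranks(post),
        }
    ).to_csv(out / "era_counts.tsv", sep="\t")
    manifest["stages"]["inequality"] = {k: ineq[k] for k in ineq}

    # -- stage: matched excess --------------------------------------------
    excess_info: dict = {}
    n_gwas = int(classes["first_gwas_year"].notna().sum())
    if n_gwas >= 1 and n_gwas < len(classes):
        ex = MatchedExcessModel(
            histories, classes, window=config.window,
            recent_window=config.recent_window,
            p_max=config.p_max, or_ci_min=config.or_ci_min,
        ).fit()
        ex.records.to_csv(out / "excess_records.tsv", sep="\t", index=False)
        ex.timeseries().to_csv(out / "excess_timeseries.tsv", sep="\t", index=False)
        excess_info["n_records"] = int(len(ex.records))
        if len(ex.records) >= 3 and ex.records["norm_excess"].var() > 0:
            t, p, mean = ex.location_test()
            excess_info.update(
                mean_raw_excess=float(ex.records["raw_excess"].mean()),
                mean_norm_excess=mean, t_stat=t, t_p=p,
            )
            covs = [
                c for c in DEFAULT_COVARIATES
                if ex.records[c].notna().sum() >= max(10, len(DEFAULT_COVARIATES) + 2)
            ]
            try:
                corr = ex.correlations([c for c in covs if c != "log10_recent"] + ["log10_recent"])
                _write_json(
                    {p_: corr.loc[p_].to_dict() for p_ in corr.index},
                    out / "excess_correlations.json",
                )
                coefs = ex.regression(covs)
                coefs.to_csv(out / "excess_regression.tsv", sep="\t")
                excess_info["regression_covariates"] = covs
                excess_info["regression_n"] = coefs.attrs.get("n")
            except ValueError as exc:
                excess_info["regression_error"] = str(exc)
        manifest["stages"]["excess"] = excess_info
    else:
        manifest["stages"]["excess"] = {"skipped": "no GWAS genes (or no controls)"}

    # -- stage: rate model --------------------------------------------------
    non_gwas = classes.index[classes["first_gwas_year"].isna()]
    model = PublicationRateModel(
        histories, fit_genes=non_gwas, fit_years=config.fit_years
    )
    fit = model.fit(starts=config.fit_starts, seed=config.seed + 4)
    _write_json(fit.to_dict(), out / "rate_params.json")
    scan = fit.hot_gene_scan(
        histories, first_gwas_year=classes["first_gwas_year"]
    )
    scan.calls.to_csv(out / "hot_calls.tsv", sep="\t", index=False)
    scan.annual_summary().to_csv(out / "hot_annual.tsv", sep="\t", index=False)
    rate_info = {
        "params": fit.params.to_dict(),
        "llf": fit.llf,
        "n_hot_calls": int(len(scan.calls)),
        "bonferroni_cutoff": scan.cutoff,
    }
    try:
        logit = hot_logistic(scan.panel())
        logit.to_csv(out / "hot_logistic.tsv", sep="\t")
        rate_info["logistic"] = {
            str(k): float(v) for k, v in logit["coef"].items()
        }
    except SeparationError as exc:
        rate_info["logistic_error"] = str(exc)
    manifest["stages"]["rate_model"] = rate_info

    # -- manifest -----------------------------------------------------------
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    _write_json(manifest, out / "manifest.json")
    logger.info("pipeline run complete: %s", out)
    return out


def report(run_dir) -> str:
    """One-page markdown summary of a completed run (partial runs get a
    partial report with warnings)."""
    run = Path(run_dir)
    lines = [f"# genepulse run report: {run.name}", ""]
    mpath = run / "manifest.json"
    if not mpath.exists():
        return "\n".join(lines + ["**warning**: no manifest found; incomplete run"])
    manifest = json.loads(mpath.read_text())
    stages = manifest.get("stages", {})

    data = stages.get("data", {})
    lines += [f"- mode: {data.get('mode', '?')}", ""]

    ineq = stages.get("inequality")
    if ineq:
        lines += [
            "## Publication inequality",
            f"- Gini (all years): {ineq['gini_total']:.3f}",
            f"- Gini pre-{ineq['cutoff_year']}: {ineq['gini_pre']:.3f}; "
            f"post: {ineq['gini_post']:.3f}",
        ]
        if "rank_shift_p" in ineq:
            lines.append(
                f"- rank shift (complex genes): U = {ineq['rank_shift_U']:.0f}, "
                f"p = {ineq['rank_shift_p']:.3g}, N = {ineq['rank_shift_n']}"
            )
        lines.append("")
    else:
        lines += ["**warning**: inequality stage missing", ""]

    ex = stages.get("excess", {})
    lines.append("## Matched-control publication excess")
    if "mean_norm_excess" in ex:
        lines += [
            f"- records: {ex['n_records']}",
            f"- mean raw excess: {ex['mean_raw_excess']:.3f} publications",
            f"- mean normalised excess: {ex['mean_norm_excess']:.3f} "
            f"(t = {ex['t_stat']:.2f}, p = {ex['t_p']:.3g})",
        ]
        rpath = run / "excess_regression.tsv"
        if rpath.exists():
            tab = pd.read_csv(rpath, sep="\t", index_col=0)
            lines += ["", "| predictor | coef | std err | p |", "|---|---|---|---|"]
            for name, row in tab.iterrows():
                lines.append(
                    f"| {name} | {row['coef']:.3f} | {row['std_err']:.3f} | {row['p_value']:.3g} |"
                )
    elif ex.get("skipped"):
        lines.append(f"- skipped: {ex['skipped']}")
    else:
        lines.append(f"- records: {ex.get('n_records', 0)} (too few for tests)")
    lines.append("")

    rm = stages.get("rate_model")
    lines.append("## Rate model and hot gene-years")
    if rm:
        pstr = ", ".join(f"{k}={v:.4g}" for k, v in rm["params"].items())
        lines += [f"- fitted parameters: {pstr}", f"- log-likelihood: {rm['llf']:.1f}"]
        n_hot = rm.get("n_hot_calls", 0)
        if n_hot:
            lines.append(f"- hot gene-years: {n_hot} (cutoff {rm['bonferroni_cutoff']:.3g})")
            apath = run / "hot_annual.tsv"
            if apath.exists():
                ann = pd.read_csv(apath, sep="\t")
                busy = ann[ann["n_hot"] > 0]
                if len(busy):
                    peak = busy.loc[busy["n_hot"].idxmax()]
                    lines.append(
                        f"- peak year: {int(peak['year'])} with {int(peak['n_hot'])} hot genes "
                        f"({int(peak['n_hot_recent_gwas'])} recent GWAS)"
                    )
        else:
            lines.append("- hot gene-years: none")
        if "logistic" in rm:
            lines.append(
                "- hot-gene logistic (coef): "
                + ", ".join(f"{k}={v:.3f}" for k, v in rm["logistic"].items())
            )
        elif "logistic_error" in rm:
            lines.append(f"- hot-gene logistic: not fitted ({rm['logistic_error']})")
    else:
        lines.append("**warning**: rate-model stage missing")
    return "\n".join(lines) + "\n"
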