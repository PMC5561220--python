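"""End-to-end study orchestration and report/plot-data exports.

:func:`run_analysis` drives the whole design for each exposure x outcome
pair: LD pruning, proxy substitution, allele harmonization, then the
requested estimators — once on all surviving SNPs and once excluding SNPs
flagged as potentially pleiotropic — and collects one report row per
(exposure, outcome, variant, method). Estimators that are infeasible on a
cell (e.g. the weighted median with fewer than three SNPs) yield an NA row
with the reason, mirroring how such cells are footnoted in published MR
tables rather than silently dropped. Every SNP's journey (kept, pruned,
proxied, harmonization-excluded, pleiotropy-excluded) is recorded in an
audit log.

The significance threshold defaults to 0.05 divided by the number of
exposures analysed — the Bonferroni-style rule that gives 0.0125 for a
four-marker study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import (
    MrEstimate,
    InfeasibleEstimatorError,
    ivw,
    ivw_correlated,
    mr_egger,
    weighted_median,
)
from .exceptions import ConfigurationError, EstimationError, MrError
from .instruments import (
    PleiotropyFlags,
    ProxyTable,
    apply_proxies,
    exclude_flagged,
    ld_prune,
    read_pleiotropy_flags,
    read_proxy_table,
)
from .summary import (
    HarmonizedSet,
    LdMatrix,
    SummaryTable,
    harmonize,
    read_ld_matrix,
    read_summary_table,
)

METHOD_NAMES = ("ivw", "wm", "egger")

REPORT_COLUMNS = (
    "exposure",
    "outcome",
    "variant",
    "method",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "significant",
    "effects_model",
    "intercept",
    "intercept_se",
    "intercept_pvalue",
    "note",
)


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure's input files and exclusion rules."""

    name: str
    path: str
    ld_path: str | None = None
    flags_path: str | None = None
    proxy_path: str | None = None
    exclude: tuple[str, ...] = ()


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    path: str


@dataclass(frozen=True)
class AnalysisConfig:
    """Full study configuration.

    ``alpha`` defaults to ``0.05 / len(exposures)`` when not given, so a
    four-exposure study tests at 0.0125. ``effects_model`` follows the IVW
    rule (``auto`` = fixed for 3 or fewer SNPs, random otherwise).
    """

    exposures: tuple[ExposureSpec, ...]
    outcomes: tuple[OutcomeSpec, ...]
    methods: tuple[str, ...] = METHOD_NAMES
    effects_model: str = "auto"
    alpha: float | None = None
    n_boot: int = 2000
    seed: int = 0
    r2_threshold: float = 0.8
    proxy_r2_threshold: float = 0.8
    palindrome_policy: str = "frequency"
    eaf_window: float = 0.08

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("need at least one exposure and one outcome")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ConfigurationError(
                f"unknown methods {sorted(unknown)}; available: {METHOD_NAMES}"
            )
        if self.alpha is not None and not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 0.05 / len(self.exposures)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        exposures = tuple(
            ExposureSpec(
                name=e["name"],
                path=e["path"],
                ld_path=e.get("ld_path"),
                flags_path=e.get("flags_path"),
                proxy_path=e.get("proxy_path"),
                exclude=tuple(e.get("exclude", ())),
            )
            for e in raw["exposures"]
        )
        outcomes = tuple(
            OutcomeSpec(name=o["name"], path=o["path"]) for o in raw["outcomes"]
        )
        kwargs = {
            k: raw[k]
            for k in (
                "effects_model",
                "alpha",
                "n_boot",
                "seed",
                "r2_threshold",
                "proxy_r2_threshold",
                "palindrome_policy",
                "eaf_window",
            )
            if k in raw
        }
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        return cls(exposures=exposures, outcomes=outcomes, **kwargs)


def _na_row(
    exposure: str, outcome: str, variant: str, method: str, n_snps: int, note: str
) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "variant": variant,
        "method": method,
        "n_snps": n_snps,
        "beta": math.nan,
        "se": math.nan,
        "ci_low": math.nan,
        "ci_high": math.nan,
        "pvalue": math.nan,
        "significant": False,
        "effects_model": None,
        "intercept": math.nan,
        "intercept_se": math.nan,
        "intercept_pvalue": math.nan,
        "note": note,
    }


def _estimate_row(
    exposure: str,
    outcome: str,
    variant: str,
    method: str,
    est: MrEstimate,
    alpha: float,
) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "variant": variant,
        "method": method,
        "n_snps": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "significant": bool(est.pvalue < alpha),
        "effects_model": est.effects_model,
        "intercept": math.nan if est.intercept is None else est.intercept,
        "intercept_se": math.nan if est.intercept_se is None else est.intercept_se,
        "intercept_pvalue": (
            math.nan if est.intercept_pvalue is None else est.intercept_pvalue
        ),
        "note": "",
    }


def _run_method(
    method: str, h: HarmonizedSet, config: AnalysisConfig
) -> MrEstimate:
    if method == "ivw":
        if h.ld is not None:
            return ivw_correlated(h)
        return ivw(h, effects_model=config.effects_model)
    if method == "wm":
        # correlated instruments are unsupported for WM; the estimator raises
        # and the pipeline records an NA row
        return weighted_median(h, n_boot=config.n_boot, seed=config.seed)
    if method == "egger":
        return mr_egger(h)
    raise ConfigurationError(f"unknown method {method!r}")


def run_analysis(
    config: AnalysisConfig, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Run the full study; returns the report table (one row per cell).

    When ``out_dir`` is given, also writes ``report.tsv``, an ``audit.tsv``
    of per-SNP decisions, and per-cell funnel/scatter data tables. The run
    is a pure function of the input files, the config and the seed.
    """
    alpha = config.effective_alpha
    rows: list[dict] = []
    audit: list[dict] = []
    exports: list[tuple[str, pd.DataFrame]] = []

    for exp_spec in config.exposures:
        exposure = read_summary_table(exp_spec.path, trait_name=exp_spec.name)
        ld = read_ld_matrix(exp_spec.ld_path) if exp_spec.ld_path else None
        flags = (
            read_pleiotropy_flags(exp_spec.flags_path) if exp_spec.flags_path else None
        )
        proxies = (
            read_proxy_table(exp_spec.proxy_path) if exp_spec.proxy_path else None
        )

        if ld is not None:
            pruned = ld_prune(exposure, ld, config.r2_threshold)
            for rs in exposure.rsids:
                if rs not in pruned:
                    audit.append(
                        {
                            "exposure": exp_spec.name,
                            "outcome": "",
                            "rsid": rs,
                            "stage": "ld_prune",
                            "action": "pruned",
                            "detail": f"r2>={config.r2_threshold} with a kept SNP",
                        }
                    )
            exposure = pruned

        for out_spec in config.outcomes:
            outcome = read_summary_table(out_spec.path, trait_name=out_spec.name)
            table = exposure
            if proxies is not None:
                table, proxy_log = apply_proxies(
                    table, set(outcome.rsids), proxies, config.proxy_r2_threshold
                )
                for entry in proxy_log:
                    if entry["action"] != "kept":
                        audit.append(
                            {
                                "exposure": exp_spec.name,
                                "outcome": out_spec.name,
                                "rsid": entry["rsid"],
                                "stage": "proxy",
                                "action": entry["action"],
                                "detail": entry["detail"],
                            }
                        )

            h_all = harmonize(
                table,
                outcome,
                palindrome_policy=config.palindrome_policy,
                eaf_window=config.eaf_window,
            )
            for rs, why in h_all.exclusions:
                audit.append(
                    {
                        "exposure": exp_spec.name,
                        "outcome": out_spec.name,
                        "rsid": rs,
                        "stage": "harmonize",
                        "action": "excluded",
                        "detail": why,
                    }
                )
            if ld is not None:
                h_all = h_all.with_ld(ld)

            variants: list[tuple[str, HarmonizedSet]] = [("all", h_all)]
            reduced_table = exclude_flagged(table, flags, exp_spec.exclude)
            removed = set(table.rsids) - set(reduced_table.rsids)
            for rs in sorted(removed):
                audit.append(
                    {
                        "exposure": exp_spec.name,
                        "outcome": out_spec.name,
                        "rsid": rs,
                        "stage": "pleiotropy",
                        "action": "excluded",
                        "detail": "flagged as potentially pleiotropic",
                    }
                )
            h_reduced = h_all.subset(
                [rs for rs in h_all.rsids if rs not in removed]
            )
            variants.append(("pleiotropy-excluded", h_reduced))

            for variant, h in variants:
                for rs in h.rsids:
                    audit.append(
                        {
                            "exposure": exp_spec.name,
                            "outcome": out_spec.name,
                            "rsid": rs,
                            "stage": f"analysis[{variant}]",
                            "action": "used",
                            "detail": "",
                        }
                    )
                cell_estimates: dict[str, MrEstimate] = {}
                for method in config.methods:
                    try:
                        est = _run_method(method, h, config)
                    except (InfeasibleEstimatorError, EstimationError) as exc:
                        rows.append(
                            _na_row(
                                exp_spec.name,
                                out_spec.name,
                                variant,
                                method,
                                h.n_snps,
                                str(exc),
                            )
                        )
                        continue
                    cell_estimates[method] = est
                    rows.append(
                        _estimate_row(
                            exp_spec.name, out_spec.name, variant, method, est, alpha
                        )
                    )
                stem = f"{exp_spec.name}__{out_spec.name}__{variant}"
                exports.append((f"funnel__{stem}", funnel_data(h)))
                if cell_estimates:
                    points, lines = scatter_data(h, list(cell_estimates.values()))
                    exports.append((f"scatter_points__{stem}", points))
                    exports.append((f"scatter_lines__{stem}", lines))

    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "report.tsv", sep="\t", index=False)
        pd.DataFrame(
            audit, columns=["exposure", "outcome", "rsid", "stage", "action", "detail"]
        ).to_csv(out_dir / "audit.tsv", sep="\t", index=False)
        for name, frame in exports:
            frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    return report


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP funnel-plot data: Wald ratio against its precision (1/SE).

    Under valid instruments the scatter is symmetric about the causal
    estimate; directional pleiotropy shows up as asymmetry concentrated in
    the low-precision SNPs.
    """
    if h.n_snps < 1:
        raise EstimationError("funnel_data: empty set")
    ratios = h.Gamma / h.gamma
    ses = h.se_Gamma / np.abs(h.gamma)
    return pd.DataFrame(
        {"rsid": list(h.rsids), "ratio": ratios, "precision": 1.0 / ses}
    )


def scatter_data(
    h: HarmonizedSet, estimates: Sequence[MrEstimate]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter-plot data: per-SNP points with 95% error bars plus one fitted
    line per method (intercept 0 for IVW and the weighted median; MR-Egger's
    own intercept for MR-Egger)."""
    points = pd.DataFrame(
        {
            "rsid": list(h.rsids),
            "gamma": h.gamma,
            "Gamma": h.Gamma,
            "se_Gamma": h.se_Gamma,
            "Gamma_low": h.Gamma - 1.96 * h.se_Gamma,
            "Gamma_high": h.Gamma + 1.96 * h.se_Gamma,
        }
    )
    lines = pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "slope": [e.beta for e in estimates],
            "intercept": [e.intercept or 0.0 for e in estimates],
        }
    )
    return points, lines
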