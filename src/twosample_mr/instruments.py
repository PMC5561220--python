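"""Instrument construction: LD pruning, proxy substitution, pleiotropy
exclusion, and instrument-strength (F-statistic) annotation.

The guiding design is the standard two-sample MR instrument recipe: start
from genome-wide-significant SNPs for the exposure, discard SNPs highly
correlated (r2 at or above a threshold, 0.8 by default) with a
better-associated SNP, substitute a highly correlated proxy when an
instrument is missing from the outcome dataset, and optionally drop SNPs
annotated as pleiotropic (associated with phenotypes that reach the outcome
other than through the exposure) in a sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .summary import LdMatrix, SnpAssociation, SummaryTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProxyRow:
    original_rsid: str
    proxy_rsid: str
    r2: float

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise ValidationError(
                f"proxy r2 for {self.original_rsid}->{self.proxy_rsid} must be in "
                f"[0, 1], got {self.r2}"
            )


@dataclass(frozen=True)
class ProxyTable:
    """Candidate proxy SNPs: rows of (original rsid, proxy rsid, r2)."""

    rows: tuple[ProxyRow, ...]

    def candidates(self, rsid: str) -> tuple[ProxyRow, ...]:
        return tuple(r for r in self.rows if r.original_rsid == rsid)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProxyTable":
        return cls(
            tuple(
                ProxyRow(str(r.original_rsid), str(r.proxy_rsid), float(r.r2))
                for r in df.itertuples()
            )
        )


def read_proxy_table(path: str | Path) -> ProxyTable:
    """Read a tab-delimited proxy file with columns original_rsid, proxy_rsid, r2."""
    df = pd.read_csv(path, sep="\t")
    missing = {"original_rsid", "proxy_rsid", "r2"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"proxy file missing columns {sorted(missing)}")
    return ProxyTable.from_frame(df)


class PleiotropyFlags:
    """Map rsid -> phenotype labels flagged as potentially pleiotropic.

    Stands in for a manual annotation search (e.g. Ensembl phenotypes):
    a SNP is flagged when it is associated with traits that could affect
    the outcome other than via the exposure.
    """

    def __init__(self, flags: Mapping[str, Iterable[str]]):
        self._flags: dict[str, tuple[str, ...]] = {}
        for rsid, labels in flags.items():
            labels = tuple(str(x) for x in labels)
            if not labels:
                raise ValidationError(f"flagged rsid {rsid} has no labels")
            self._flags[str(rsid)] = labels

    def labels(self, rsid: str) -> tuple[str, ...]:
        return self._flags.get(rsid, ())

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._flags

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(self._flags)


def read_pleiotropy_flags(path: str | Path) -> PleiotropyFlags:
    """Read a tab-delimited flags file with columns rsid, label (one row per label)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"rsid", "label"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"flags file missing columns {sorted(missing)}")
    flags: dict[str, list[str]] = {}
    for row in df.itertuples():
        flags.setdefault(str(row.rsid), []).append(str(row.label))
    return PleiotropyFlags(flags)


def ld_prune(
    table: SummaryTable, ld: LdMatrix, r2_threshold: float = 0.8
) -> SummaryTable:
    """Greedy LD pruning keeping the SNPs with the smallest p-values.

    SNPs are visited in ascending p-value order (ties broken by rsid) and
    accepted only when their squared correlation with every already accepted
    SNP is below ``r2_threshold``. The returned table preserves the input
    row order of the survivors.
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    index = {rs: i for i, rs in enumerate(ld.rsids)}
    for rs in table.rsids:
        if rs not in index:
            raise ValidationError(f"rsid {rs} absent from LD matrix")
    accepted: list[str] = []
    for assoc in sorted(table, key=lambda a: (a.pvalue, a.rsid)):
        i = index[assoc.rsid]
        if all(ld.r[i, index[kept]] ** 2 < r2_threshold for kept in accepted):
            accepted.append(assoc.rsid)
    dropped = len(table) - len(accepted)
    if dropped:
        logger.info(
            "ld_prune: discarded %d of %d SNPs at r2>=%s", dropped, len(table), r2_threshold
        )
    return table.subset(accepted)


def apply_proxies(
    table: SummaryTable,
    available: Iterable[str],
    proxies: ProxyTable,
    proxy_r2_threshold: float = 0.8,
) -> tuple[SummaryTable, list[dict]]:
    """Substitute proxies for instruments missing from the outcome dataset.

    Each SNP in ``table`` that is absent from ``available`` is replaced by
    its highest-r2 proxy that is available and satisfies
    ``r2 >= proxy_r2_threshold`` (ties broken by proxy rsid). SNPs with no
    eligible proxy are dropped. Nothing is fatal; every outcome is recorded
    in the returned log as dicts with keys rsid/action/detail.

    The substituted record keeps the original SNP's exposure beta and SE
    under the proxy's rsid — the proxy's own published association with the
    outcome is then used at harmonization, mirroring direct proxy
    substitution without r2 attenuation correction.
    """
    available = set(available)
    taken = set(table.rsids) | set()
    kept: list[SnpAssociation] = []
    log: list[dict] = []
    for assoc in table:
        if assoc.rsid in available:
            kept.append(assoc)
            log.append({"rsid": assoc.rsid, "action": "kept", "detail": ""})
            continue
        eligible = [
            row
            for row in proxies.candidates(assoc.rsid)
            if row.r2 >= proxy_r2_threshold
            and row.proxy_rsid in available
            and row.proxy_rsid not in taken
        ]
        if not eligible:
            log.append(
                {
                    "rsid": assoc.rsid,
                    "action": "dropped",
                    "detail": "unavailable and no eligible proxy "
                    f"(r2>={proxy_r2_threshold})",
                }
            )
            continue
        best = max(eligible, key=lambda row: (row.r2, row.proxy_rsid))
        taken.add(best.proxy_rsid)
        kept.append(
            SnpAssociation(
                rsid=best.proxy_rsid,
                effect_allele=assoc.effect_allele,
                other_allele=assoc.other_allele,
                beta=assoc.beta,
                se=assoc.se,
                pvalue=assoc.pvalue,
                eaf=assoc.eaf,
                n=assoc.n,
            )
        )
        log.append(
            {
                "rsid": assoc.rsid,
                "action": "proxied",
                "detail": f"substituted {best.proxy_rsid} (r2={best.r2})",
            }
        )
    return SummaryTable(table.trait_name, tuple(kept)), log


def exclude_flagged(
    table: SummaryTable,
    flags: PleiotropyFlags | None = None,
    exclude: Sequence[str] = (),
) -> SummaryTable:
    """Drop SNPs named in ``exclude`` (by rsid or by flagged label).

    An entry of ``exclude`` removes a SNP either because it equals the
    SNP's rsid or because the SNP carries that label in ``flags``. rsids in
    ``exclude`` that match nothing produce a warning, not an error.
    """
    exclude_set = set(exclude)
    flags = flags or PleiotropyFlags({})
    kept, removed = [], []
    for assoc in table:
        labels = set(flags.labels(assoc.rsid))
        if assoc.rsid in exclude_set or labels & exclude_set:
            removed.append(assoc.rsid)
        else:
            kept.append(assoc)
    matched = set(removed) | {
        e for e in exclude_set if any(e in flags.labels(a.rsid) for a in table)
    }
    for entry in exclude_set - matched:
        if entry.startswith("rs"):
            logger.warning("exclude_flagged: %s not in table, ignored", entry)
    if removed:
        logger.info("exclude_flagged: removed %d SNPs: %s", len(removed), removed)
    return SummaryTable(table.trait_name, tuple(kept))


def f_statistic(assoc: SnpAssociation) -> tuple[float, float]:
    """Per-SNP variance explained and instrument-strength F-statistic.

    Assumes the exposure is variance-standardized, under which the variance
    explained by a SNP with effect-allele frequency p and per-allele effect
    beta is ``R2 = 2 p (1 - p) beta^2`` and ``F = R2 (n - 2) / (1 - R2)``.
    If the published betas are on an unstandardized scale, divide them by
    the trait SD first. F below 10 is conventionally taken to indicate weak
    instruments.

    Returns ``(R2, F)``.
    """
    if assoc.eaf is None:
        raise ConfigurationError(f"{assoc.rsid}: eaf required for F-statistic")
    if assoc.n is None:
        raise ConfigurationError(f"{assoc.rsid}: sample size n required for F-statistic")
    r2 = 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2
    if r2 >= 1:
        raise ValidationError(
            f"{assoc.rsid}: implied R2={r2:.4g} >= 1; beta/eaf inconsistent with a "
            "standardized trait"
        )
    f = r2 * (assoc.n - 2) / (1.0 - r2)
    return r2, f


def strength_report(table: SummaryTable, f_threshold: float = 10.0) -> pd.DataFrame:
    """Per-SNP instrument-strength report: R2, F, and a weak-instrument flag."""
    rows = []
    for assoc in table:
        r2, f = f_statistic(assoc)
        rows.append(
            {"rsid": assoc.rsid, "r2": r2, "F": f, "weak": f < f_threshold}
        )
    return pd.DataFrame(rows, columns=["rsid", "r2", "F", "weak"])
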