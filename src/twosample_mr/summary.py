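"""GWAS summary-statistic containers, file I/O, and allele harmonization.

The in-memory model is deliberately small: a :class:`SnpAssociation` holds
one SNP's published association with one trait (effect/other allele, effect
allele frequency, beta, SE, p, N), a :class:`SummaryTable` is an ordered,
rsid-unique collection of them, and an :class:`LdMatrix` is a signed
correlation matrix over a set of rsids. :func:`harmonize` pairs an exposure
table with an outcome table on a common effect-allele orientation, which is
the precondition for every two-sample MR estimator downstream.

Files are plain tab-delimited text with a header row; ``NA`` marks missing
optional fields. The LD file is a square matrix whose first row and first
column both carry the rsids. The LD entries are signed correlations r, not
r-squared: the GLS covariance for correlated instruments needs the sign, and
tools that report r2 (e.g. SNAP) leave the sign conversion to the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInstrumentSetError,
    HarmonizationError,
    ValidationError,
)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistic files
SUMMARY_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the additive per-effect-allele effect on the trait in the
    units the source GWAS published (e.g. ln(mg/L) for CRP, SD units for
    BMD). ``eaf`` and ``n`` are optional; operations that need them
    (F-statistics, frequency-based palindrome resolution) raise a targeted
    error when they are absent rather than guessing.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        for allele in (self.effect_allele, self.other_allele):
            if allele not in VALID_ALLELES:
                raise ValidationError(
                    f"{self.rsid}: allele {allele!r} is not one of A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.rsid}: effect and other allele are both {self.effect_allele}"
            )
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.rsid}: se must be positive, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta must be finite, got {self.beta}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(
                f"{self.rsid}: p-value must be in (0, 1], got {self.pvalue}"
            )
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.rsid}: eaf must lie in [0, 1], got {self.eaf}")
        if self.n is not None:
            if int(self.n) != self.n or self.n <= 0:
                raise ValidationError(
                    f"{self.rsid}: n must be a positive integer, got {self.n}"
                )
            object.__setattr__(self, "n", int(self.n))

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G SNPs, whose strand cannot be told from alleles."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "SnpAssociation":
        """Re-express the association for the other allele.

        Swaps the allele labels, negates beta and replaces eaf by 1 - eaf.
        Applying this twice returns the original record exactly.
        """
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def complemented(self) -> "SnpAssociation":
        """Map both alleles to the opposite strand; effects unchanged."""
        return replace(
            self,
            effect_allele=COMPLEMENT[self.effect_allele],
            other_allele=COMPLEMENT[self.other_allele],
        )


@dataclass(frozen=True)
class SummaryTable:
    """Ordered collection of :class:`SnpAssociation` with unique rsids."""

    trait_name: str
    associations: tuple[SnpAssociation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "associations", tuple(self.associations))
        seen: set[str] = set()
        for assoc in self.associations:
            if assoc.rsid in seen:
                raise ValidationError(
                    f"duplicate rsid {assoc.rsid} in table {self.trait_name!r}"
                )
            seen.add(assoc.rsid)

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.associations)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(a.rsid for a in self.associations)

    def get(self, rsid: str) -> SnpAssociation:
        for assoc in self.associations:
            if assoc.rsid == rsid:
                return assoc
        raise KeyError(rsid)

    def __contains__(self, rsid: str) -> bool:
        return any(a.rsid == rsid for a in self.associations)

    def subset(self, rsids: Iterable[str]) -> "SummaryTable":
        """Keep only ``rsids``, preserving this table's row order."""
        keep = set(rsids)
        return SummaryTable(
            self.trait_name, tuple(a for a in self.associations if a.rsid in keep)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": a.rsid,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "eaf": a.eaf,
                "beta": a.beta,
                "se": a.se,
                "pvalue": a.pvalue,
                "n": a.n,
            }
            for a in self.associations
        ]
        return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


@dataclass(frozen=True)
class LdMatrix:
    """Signed pairwise correlation matrix over an ordered set of rsids.

    Invariants checked at construction: square and matching the rsid count,
    symmetric within 1e-10 (then symmetrized by averaging), unit diagonal
    within 1e-10, entries in [-1, 1], positive semi-definite within 1e-8.
    """

    rsids: tuple[str, ...]
    r: np.ndarray = field(repr=False)

    _SYM_TOL = 1e-10
    _PSD_TOL = 1e-8

    def __post_init__(self) -> None:
        rsids = tuple(self.rsids)
        object.__setattr__(self, "rsids", rsids)
        if len(set(rsids)) != len(rsids):
            raise ValidationError("duplicate rsids in LD matrix")
        r = np.asarray(self.r, dtype=float)
        k = len(rsids)
        if r.shape != (k, k):
            raise ValidationError(
                f"LD matrix shape {r.shape} does not match {k} rsids"
            )
        if np.max(np.abs(r - r.T)) > self._SYM_TOL:
            raise ValidationError("LD matrix asymmetry exceeds 1e-10")
        r = (r + r.T) / 2.0
        if np.max(np.abs(np.diag(r) - 1.0)) > self._SYM_TOL:
            raise ValidationError("LD matrix diagonal deviates from 1 beyond 1e-10")
        np.fill_diagonal(r, 1.0)
        if np.max(np.abs(r)) > 1.0 + self._SYM_TOL:
            raise ValidationError("LD matrix has an entry outside [-1, 1]")
        np.clip(r, -1.0, 1.0, out=r)
        eigmin = float(np.linalg.eigvalsh(r).min()) if k else 1.0
        if eigmin < -self._PSD_TOL:
            raise ValidationError(
                f"LD matrix is not positive semi-definite (min eigenvalue {eigmin:.3e})"
            )
        r.setflags(write=False)
        object.__setattr__(self, "r", r)

    def __len__(self) -> int:
        return len(self.rsids)

    def subset(self, rsids: Sequence[str]) -> "LdMatrix":
        """Restrict to ``rsids`` in the given order."""
        index = {rs: i for i, rs in enumerate(self.rsids)}
        try:
            idx = [index[rs] for rs in rsids]
        except KeyError as exc:
            raise ValidationError(f"rsid {exc.args[0]} absent from LD matrix") from None
        return LdMatrix(tuple(rsids), self.r[np.ix_(idx, idx)])

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LdMatrix":
        return cls(tuple(rsids), np.eye(len(rsids)))


@dataclass(frozen=True)
class HarmonizedSet:
    """Per-SNP paired exposure/outcome effects on a common effect allele.

    Arrays are aligned: element j carries SNP j's exposure effect gamma_j
    with SE se_gamma_j and outcome effect Gamma_j with SE se_Gamma_j. The
    optional ``ld`` matrix is restricted to exactly these rsids, in order.
    ``exclusions`` records the SNPs that did not survive harmonization and
    why.
    """

    rsids: tuple[str, ...]
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    ld: LdMatrix | None = None
    exclusions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rsids", tuple(self.rsids))
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.rsids),):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({len(self.rsids)},)"
                )
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if np.any(self.se_gamma <= 0) or np.any(self.se_Gamma <= 0):
            raise ValidationError("all standard errors must be positive")
        if self.ld is not None and self.ld.rsids != self.rsids:
            raise ValidationError("ld rsids do not match harmonized rsids in order")
        object.__setattr__(self, "exclusions", tuple(self.exclusions))

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    def with_ld(self, ld: LdMatrix) -> "HarmonizedSet":
        """Attach an LD matrix, restricted and reordered to this set's rsids."""
        return replace(self, ld=ld.subset(self.rsids))

    def without_ld(self) -> "HarmonizedSet":
        return replace(self, ld=None)

    def subset(self, rsids: Sequence[str]) -> "HarmonizedSet":
        keep = [rs for rs in self.rsids if rs in set(rsids)]
        idx = [self.rsids.index(rs) for rs in keep]
        return HarmonizedSet(
            tuple(keep),
            self.gamma[idx],
            self.se_gamma[idx],
            self.Gamma[idx],
            self.se_Gamma[idx],
            ld=None if self.ld is None else self.ld.subset(keep),
            exclusions=self.exclusions,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": list(self.rsids),
                "gamma": self.gamma,
                "se_gamma": self.se_gamma,
                "Gamma": self.Gamma,
                "se_Gamma": self.se_Gamma,
            }
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
) -> SummaryTable:
    """Read a tab-delimited summary-statistic file.

    ``column_map`` maps the canonical names (``rsid``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``) to the
    file's header names; canonical names present in the file need no entry.
    ``eaf`` and ``n`` are optional columns; ``NA`` marks missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    for canonical in SUMMARY_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            resolved[canonical] = source
        elif canonical in column_map or canonical not in ("eaf", "n"):
            raise ConfigurationError(
                f"column {source!r} (for {canonical!r}) not found in {path.name}; "
                f"file has columns {list(df.columns)}"
            )
    associations = []
    for i, row in df.iterrows():
        def cell(canonical: str) -> str | None:
            if canonical not in resolved:
                return None
            value = row[resolved[canonical]]
            return None if pd.isna(value) else value

        try:
            associations.append(
                SnpAssociation(
                    rsid=str(cell("rsid")),
                    effect_allele=str(cell("effect_allele")),
                    other_allele=str(cell("other_allele")),
                    beta=float(cell("beta")),
                    se=float(cell("se")),
                    pvalue=float(cell("pvalue")),
                    eaf=None if cell("eaf") is None else float(cell("eaf")),
                    n=None if cell("n") is None else int(float(cell("n"))),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"{path.name} row {i + 2}: {exc}") from None
            raise ValidationError(
                f"{path.name} row {i + 2}: cannot coerce values ({exc})"
            ) from None
    return SummaryTable(trait_name or path.stem, tuple(associations))


def write_summary_table(table: SummaryTable, path: str | Path) -> None:
    """Write the canonical tab-delimited format; round-trips all numerics.

    Floats are written with :func:`repr`, so reading the file back
    reproduces every value bit-for-bit.
    """
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for a in table:
        lines.append(
            "\t".join(
                [
                    a.rsid,
                    a.effect_allele,
                    a.other_allele,
                    "NA" if a.eaf is None else repr(float(a.eaf)),
                    repr(float(a.beta)),
                    repr(float(a.se)),
                    repr(float(a.pvalue)),
                    "NA" if a.n is None else str(a.n),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a square tab-delimited signed-correlation matrix.

    The first row and the first column both carry the rsids and must agree.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    rsids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != rsids:
        raise ValidationError(
            f"{path.name}: row and column rsids differ (matrix must be square "
            "with identical header row and first column)"
        )
    return LdMatrix(rsids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    lines = ["\t".join(("rsid",) + ld.rsids)]
    for rsid, row in zip(ld.rsids, ld.r):
        lines.append("\t".join([rsid] + [repr(float(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _align_outcome(
    exp: SnpAssociation,
    out: SnpAssociation,
    palindrome_policy: str,
    eaf_window: float,
) -> tuple[SnpAssociation | None, str | None]:
    """Return the outcome record re-expressed on the exposure's effect allele,
    or (None, reason) when the SNP must be excluded."""
    pair = (out.effect_allele, out.other_allele)
    direct = (exp.effect_allele, exp.other_allele)
    swapped = (exp.other_allele, exp.effect_allele)

    if exp.is_palindromic:
        # complementing a palindromic pair reproduces the swapped pair, so
        # allele labels alone cannot settle the orientation
        if pair not in (direct, swapped):
            return None, "incompatible alleles"
        if palindrome_policy == "drop":
            return None, "palindromic SNP (policy=drop)"
        if palindrome_policy == "keep":
            return (out if pair == direct else out.flipped()), None
        if palindrome_policy == "frequency":
            if exp.eaf is None or out.eaf is None:
                raise ConfigurationError(
                    f"{exp.rsid}: palindrome_policy='frequency' needs eaf in both "
                    "exposure and outcome tables"
                )
            out_eaf = out.eaf if pair == direct else 1.0 - out.eaf
            if abs(exp.eaf - 0.5) <= eaf_window and abs(out_eaf - 0.5) <= eaf_window:
                return None, "ambiguous palindrome (both eafs near 0.5)"
            aligned = out if pair == direct else out.flipped()
            if (exp.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
                aligned = aligned.flipped()
            return aligned, None
        raise ConfigurationError(
            f"unknown palindrome_policy {palindrome_policy!r}; "
            "expected drop, frequency, or keep"
        )

    if pair == direct:
        return out, None
    if pair == swapped:
        return out.flipped(), None
    comp = out.complemented()
    pair = (comp.effect_allele, comp.other_allele)
    if pair == direct:
        return comp, None
    if pair == swapped:
        return comp.flipped(), None
    return None, "incompatible alleles"


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_policy: str = "frequency",
    eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Pair exposure and outcome effects on a common effect allele.

    For each rsid shared between the tables the outcome record is matched to
    the exposure's allele pair: identical alleles are kept as published,
    swapped alleles sign-flip the outcome beta (and mirror its eaf), and a
    strand-complement match is complemented first. Palindromic (A/T, C/G)
    SNPs are handled per ``palindrome_policy``:

    ``drop``
        excluded outright;
    ``frequency`` (default)
        oriented so the effect-allele frequencies agree across samples, and
        excluded as ambiguous when both frequencies lie within
        ``eaf_window`` of 0.5;
    ``keep``
        assumed to be reported on the same strand already.

    SNPs with irreconcilable allele pairs (e.g. A/C vs A/G) are excluded
    with a reason, not fatal. Raises :class:`HarmonizationError` when the
    tables share no rsid and :class:`EmptyInstrumentSetError` when no shared
    SNP survives.
    """
    shared = [rs for rs in exposure.rsids if rs in outcome]
    if not shared:
        raise HarmonizationError(
            f"no rsids shared between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )
    rsids, gamma, se_gamma, Gamma, se_Gamma = [], [], [], [], []
    exclusions: list[tuple[str, str]] = []
    for rs in shared:
        exp, out = exposure.get(rs), outcome.get(rs)
        aligned, reason = _align_outcome(exp, out, palindrome_policy, eaf_window)
        if aligned is None:
            exclusions.append((rs, reason or "excluded"))
            continue
        rsids.append(rs)
        gamma.append(exp.beta)
        se_gamma.append(exp.se)
        Gamma.append(aligned.beta)
        se_Gamma.append(aligned.se)
    if not rsids:
        raise EmptyInstrumentSetError(
            "no SNPs survived harmonization: "
            + "; ".join(f"{rs}: {why}" for rs, why in exclusions)
        )
    return HarmonizedSet(
        tuple(rsids),
        np.array(gamma),
        np.array(se_gamma),
        np.array(Gamma),
        np.array(se_Gamma),
        exclusions=tuple(exclusions),
    )
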