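"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data layout of a two-sample MR study: an
exposure GWAS and one or more outcome GWAS, sharing the same J SNPs but
measured in disjoint samples. For SNP j with effect-allele frequency
``eaf_j`` and true exposure effect ``gamma_j``, a variance-standardized
trait measured in n individuals yields an estimated per-allele effect with
sampling SE approximately ``1 / sqrt(2 eaf_j (1 - eaf_j) n)``; the true
outcome effect is ``Gamma_j = theta * gamma_j + alpha_j`` where theta is
the causal effect and alpha_j the SNP's direct (pleiotropic) effect on the
outcome. Observed effects add normal noise with those SEs, correlated
within configured LD blocks inside each sample (shared subjects) but
independent between the two samples. Pleiotropic effects are drawn
independently of instrument strength, so the InSIDE assumption holds unless
``inside_violation`` is set.

Named scenarios (:func:`scenario`) pin down the study conditions used
throughout the test-bench: 20 instruments, exposure and outcome sample
sizes of 50 000, exposure effects uniform on [0.05, 0.3] and allele
frequencies uniform on [0.1, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .summary import (
    HarmonizedSet,
    LdMatrix,
    SnpAssociation,
    SummaryTable,
    harmonize,
    write_ld_matrix,
    write_summary_table,
)

# allele pairs that are not strand-ambiguous, so harmonization is exact
_ALLELE_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)


@dataclass(frozen=True)
class Pleiotropy:
    """Law of the per-SNP direct effects alpha_j.

    ``none``: alpha_j = 0. ``balanced(sd)``: alpha_j ~ N(0, sd^2).
    ``directional(mean, sd)``: alpha_j ~ N(mean, sd^2). ``fraction``
    restricts the law to the first ``round(fraction * J)`` SNPs (the
    invalid instruments); the rest stay valid.
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy kind {self.kind!r}")
        if self.sd < 0:
            raise ConfigurationError("pleiotropy sd must be non-negative")
        if self.kind == "balanced" and self.mean != 0:
            raise ConfigurationError("balanced pleiotropy has zero mean by definition")
        if not (0 <= self.fraction <= 1):
            raise ConfigurationError("pleiotropy fraction must be in [0, 1]")

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none")

    @classmethod
    def balanced(cls, sd: float, fraction: float = 1.0) -> "Pleiotropy":
        return cls("balanced", 0.0, sd, fraction)

    @classmethod
    def directional(cls, mean: float, sd: float, fraction: float = 1.0) -> "Pleiotropy":
        return cls("directional", mean, sd, fraction)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated two-sample study.

    ``gamma_law`` and ``maf_law`` are (low, high) bounds of uniform laws for
    the true exposure effects and effect-allele frequencies. ``ld_blocks``
    lists (block size, within-block r) pairs; SNPs not covered by a block
    are independent. ``seed`` is mandatory — the same config yields
    byte-identical output files.
    """

    n_snps: int = 20
    theta: float = 0.0
    gamma_law: tuple[float, float] = (0.05, 0.3)
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    ld_blocks: tuple[tuple[int, float], ...] = ()
    maf_law: tuple[float, float] = (0.1, 0.5)
    inside_violation: float = 0.0
    outcome_names: tuple[str, ...] = ("outcome",)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be at least 1")
        if self.seed is None:
            raise ConfigurationError("a seed is required")
        if self.n_exposure < 3 or self.n_outcome < 3:
            raise ConfigurationError("sample sizes must be at least 3")
        for size, r in self.ld_blocks:
            if size < 1 or not (abs(r) < 1):
                raise ConfigurationError(
                    f"ld block ({size}, {r}) invalid: need size >= 1 and |r| < 1"
                )
        if sum(size for size, _ in self.ld_blocks) > self.n_snps:
            raise ConfigurationError("ld blocks cover more SNPs than n_snps")
        if not (-1 < self.inside_violation < 1):
            raise ConfigurationError("inside_violation must be a correlation in (-1, 1)")
        if not self.outcome_names:
            raise ConfigurationError("at least one outcome name is required")


@dataclass(frozen=True)
class SimulationTruth:
    theta: float
    gamma: np.ndarray  # true per-SNP exposure effects
    alpha: np.ndarray  # true per-SNP direct (pleiotropic) effects
    eaf: np.ndarray


@dataclass(frozen=True)
class SimulatedStudy:
    """One simulated study: exposure table, outcome table(s), LD, and truth."""

    config: SimulationConfig
    exposure: SummaryTable
    outcomes: Mapping[str, SummaryTable]
    ld: LdMatrix
    truth: SimulationTruth

    @property
    def outcome(self) -> SummaryTable:
        """The first (or only) outcome table."""
        return next(iter(self.outcomes.values()))

    def harmonized(self, outcome_name: str | None = None) -> HarmonizedSet:
        """Harmonize the exposure against one outcome (alleles are aligned by
        construction, so policy ``keep`` is exact)."""
        outcome = (
            self.outcome if outcome_name is None else self.outcomes[outcome_name]
        )
        return harmonize(self.exposure, outcome, palindrome_policy="keep")


def _ld_correlation(config: SimulationConfig) -> np.ndarray:
    """Block-diagonal correlation over the J SNPs; identity off the blocks."""
    R = np.eye(config.n_snps)
    start = 0
    for size, r in config.ld_blocks:
        block = np.full((size, size), r)
        np.fill_diagonal(block, 1.0)
        R[start : start + size, start : start + size] = block
        start += size
    return R


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _table(
    name: str,
    rsids: list[str],
    alleles: list[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> SummaryTable:
    pvals = _pvalues(beta, se)
    return SummaryTable(
        name,
        tuple(
            SnpAssociation(
                rsid=rsids[j],
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                beta=float(beta[j]),
                se=float(se[j]),
                pvalue=float(pvals[j]),
                eaf=float(eaf[j]),
                n=n,
            )
            for j in range(len(rsids))
        ),
    )


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Draw one two-sample summary-statistic study from ``config``.

    Deterministic given ``config.seed``. Raises
    :class:`~twosample_mr.exceptions.ConfigurationError` when an LD block
    correlation is not positive definite.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps
    rsids = [f"rs{j + 1:05d}" for j in range(J)]
    alleles = [
        tuple(_ALLELE_PAIRS[k]) for k in rng.integers(0, len(_ALLELE_PAIRS), size=J)
    ]
    eaf = rng.uniform(*config.maf_law, size=J)
    gamma = rng.uniform(*config.gamma_law, size=J)

    # pleiotropic direct effects; InSIDE holds unless inside_violation couples
    # alpha to instrument strength
    alpha = np.zeros(J)
    if config.pleiotropy.kind != "none":
        m = int(round(config.pleiotropy.fraction * J))
        z = rng.normal(size=m)
        if config.inside_violation:
            g_std = (gamma[:m] - np.mean(gamma[:m])) / (np.std(gamma[:m]) or 1.0)
            rho = config.inside_violation
            z = rho * g_std + np.sqrt(1 - rho**2) * z
        alpha[:m] = config.pleiotropy.mean + config.pleiotropy.sd * z

    R = _ld_correlation(config)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ConfigurationError("LD block correlation is not positive definite")

    se_gamma = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_exposure)
    gamma_hat = gamma + se_gamma * (L @ rng.normal(size=J))
    exposure = _table(
        "exposure", rsids, alleles, eaf, gamma_hat, se_gamma, config.n_exposure
    )

    se_Gamma = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_outcome)
    Gamma = config.theta * gamma + alpha
    outcomes = {}
    for name in config.outcome_names:
        Gamma_hat = Gamma + se_Gamma * (L @ rng.normal(size=J))
        outcomes[name] = _table(
            name, rsids, alleles, eaf, Gamma_hat, se_Gamma, config.n_outcome
        )

    return SimulatedStudy(
        config=config,
        exposure=exposure,
        outcomes=outcomes,
        ld=LdMatrix(tuple(rsids), R),
        truth=SimulationTruth(config.theta, gamma, alpha, eaf),
    )


_SCENARIOS: dict[str, tuple[SimulationConfig, str]] = {}


def _register(name: str, config: SimulationConfig, doc: str) -> None:
    _SCENARIOS[name] = (config, doc)


_register(
    "null",
    SimulationConfig(theta=0.0, seed=101),
    "no causal effect, no pleiotropy: every estimator should be null",
)
_register(
    "causal",
    SimulationConfig(theta=0.3, seed=102),
    "causal effect 0.3, all instruments valid",
)
_register(
    "balanced",
    SimulationConfig(theta=0.3, pleiotropy=Pleiotropy.balanced(0.05), seed=103),
    "causal effect 0.3 plus zero-mean pleiotropy (sd 0.05) on every SNP",
)
_register(
    "directional",
    SimulationConfig(theta=0.3, pleiotropy=Pleiotropy.directional(0.05, 0.01), seed=104),
    "causal effect 0.3 plus directional pleiotropy (mean 0.05, sd 0.01) on every SNP",
)
_register(
    "thirty-percent-invalid",
    SimulationConfig(
        theta=0.3,
        pleiotropy=Pleiotropy.directional(0.05, 0.01, fraction=0.3),
        seed=105,
    ),
    "6 of 20 SNPs carry directional pleiotropy; the weighted median should "
    "stay near the truth while IVW is pulled away",
)
_register(
    "correlated-blocks",
    SimulationConfig(theta=0.3, ld_blocks=((5, 0.6), (5, 0.4)), seed=106),
    "two LD blocks (r 0.6 and 0.4) among the 20 SNPs; exercise the GLS path",
)
_register(
    "paper-shaped",
    SimulationConfig(
        theta=0.0,
        outcome_names=("forearm", "femoral_neck", "lumbar_spine"),
        seed=107,
    ),
    "one 20-SNP exposure against three skeletal-site outcomes, no causal effect",
)


def scenario(name: str, seed: int | None = None) -> SimulationConfig:
    """Return a named preset configuration (optionally reseeded).

    Raises :class:`~twosample_mr.exceptions.ConfigurationError` listing the
    available scenario names when ``name`` is unknown.
    """
    try:
        config, _ = _SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(_SCENARIOS))}"
        ) from None
    return config if seed is None else replace(config, seed=seed)


def scenario_names() -> tuple[str, ...]:
    return tuple(_SCENARIOS)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study's tables and LD matrix as tab-delimited files.

    Returns a mapping of logical names to file paths. Byte-identical for
    equal configs (same seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["exposure"] = out_dir / "exposure.tsv"
    write_summary_table(study.exposure, paths["exposure"])
    for name, table in study.outcomes.items():
        paths[name] = out_dir / f"outcome_{name}.tsv"
        write_summary_table(table, paths[name])
    paths["ld"] = out_dir / "ld.tsv"
    write_ld_matrix(study.ld, paths["ld"])
    return paths
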