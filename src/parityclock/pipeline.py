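"""Applied workflow: from phylogeny summaries and sequence pairs to TMRCAs.

The pipeline ingests (a) a per-site transition-count table and a list of
transversion sites extracted from a detailed reference phylogeny, and
(b) a pair of aligned sequences.  Sites where a transversion occurred --
either anywhere in the phylogeny or between the pair -- violate the
transitions-only model and are masked out, along with sites made unusable
by gaps or ambiguity codes.  The surviving ``(X, Z)`` vectors feed the
estimators; the resulting scaled distance is converted to years with a
substitution-rate calibration, and TMRCAs from many modern-sequence
comparisons are combined by uniform averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import estimators, io
from .errors import ContractError, EstimationError, ParseError
from .estimators import DistanceEstimate
from .model import ParityProblem

__all__ = [
    "SAME", "TRANSITION", "TRANSVERSION", "UNUSABLE",
    "PhylogenySummary", "PairDiff", "CalibrationConfig",
    "load_phylogeny_summary", "diff_pair", "mask_and_assemble",
    "estimate_distance", "bootstrap_sd",
    "calibrate", "tmrca", "aggregate_tmrca",
]

# per-site classification codes for a sequence pair
SAME = 0
TRANSITION = 1
TRANSVERSION = 2
UNUSABLE = 3

# base codes chosen so that the transition partner is code ^ 1
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"AGCT", (0, 1, 2, 3)):
    _BASE_CODE[_b] = _c


@dataclass(frozen=True)
class PhylogenySummary:
    """Per-site transition counts and transversion sites from a phylogeny.

    ``transition_counts[i]`` is the number of transitions annotated at
    1-based site ``i + 1`` across the whole tree; ``transversion_sites``
    holds the 1-based indices of sites where at least one transversion
    occurred anywhere in the tree.
    """

    transition_counts: np.ndarray
    transversion_sites: frozenset[int]
    n_sites: int

    def __post_init__(self):
        counts = np.asarray(self.transition_counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size != self.n_sites:
            raise ContractError("transition_counts length must equal n_sites")
        if np.any(counts < 0):
            raise ContractError("transition counts must be non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "transition_counts", counts)
        tv = frozenset(int(s) for s in self.transversion_sites)
        if tv and (min(tv) < 1 or max(tv) > self.n_sites):
            raise ContractError("transversion_sites must lie in 1..n_sites")
        object.__setattr__(self, "transversion_sites", tv)


@dataclass(frozen=True)
class PairDiff:
    """Per-site classification of an aligned sequence pair."""

    classification: np.ndarray

    def __post_init__(self):
        cls = np.asarray(self.classification, dtype=np.int8)
        cls.setflags(write=False)
        object.__setattr__(self, "classification", cls)

    @property
    def n(self) -> int:
        return self.classification.size

    @property
    def usable(self) -> np.ndarray:
        """Sites on which a parity observation is defined."""
        return (self.classification == SAME) | (self.classification == TRANSITION)


@dataclass(frozen=True)
class CalibrationConfig:
    """Constants mapping scaled distances to years.

    ``mu`` is the per-site per-year substitution rate of the mtDNA coding
    region; ``mean_subs_per_site`` is the average number of substitutions
    per site accumulated over the whole reference phylogeny, so their
    ratio is the total tree length in years.  Sample ages are in years
    before present.
    """

    mu: float = 1.57e-8
    mean_subs_per_site: float = 1.4
    sample_age_1: float = 0.0
    sample_age_2: float = 0.0

    def __post_init__(self):
        if not (self.mu > 0 and self.mean_subs_per_site > 0):
            raise ContractError("mu and mean_subs_per_site must be positive")
        if self.sample_age_1 < 0 or self.sample_age_2 < 0:
            raise ContractError("sample ages must be non-negative")

    @property
    def tree_length_years(self) -> float:
        return self.mean_subs_per_site / self.mu


def load_phylogeny_summary(counts_file, transversions_file) -> PhylogenySummary:
    """Load and validate a phylogeny summary from its two text files."""
    counts = io.read_count_table(counts_file)
    tv = io.read_transversion_sites(transversions_file)
    if tv and max(tv) > counts.size:
        raise ParseError(
            f"{transversions_file}: site {max(tv)} exceeds table length {counts.size}"
        )
    return PhylogenySummary(counts, frozenset(tv), counts.size)


def diff_pair(seq_a: str, seq_b: str) -> PairDiff:
    """Classify each aligned site of a sequence pair.

    Equal valid bases -> same; A<->G or C<->T -> transition; any
    purine<->pyrimidine change -> transversion; N, gaps, and any other
    ambiguity code -> unusable.  Case-insensitive.
    """
    if len(seq_a) != len(seq_b):
        raise ContractError(
            f"aligned sequences must have equal length ({len(seq_a)} != {len(seq_b)})"
        )
    if len(seq_a) == 0:
        raise ContractError("sequences must be non-empty")
    a = _BASE_CODE[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    b = _BASE_CODE[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    valid = (a != 255) & (b != 255)
    cls = np.full(len(seq_a), UNUSABLE, dtype=np.int8)
    cls[valid & (a == b)] = SAME
    cls[valid & ((a ^ 1) == b)] = TRANSITION
    cls[valid & (a != b) & ((a ^ 1) != b)] = TRANSVERSION
    return PairDiff(cls)


def mask_and_assemble(summary: PhylogenySummary, diff: PairDiff) -> ParityProblem:
    """Drop transversion and unusable sites; assemble the (X, Z) problem.

    A site survives only if it is outside the phylogeny's transversion
    sites and classified same/transition in the pair.  Surviving sites
    retain their original 1-based coordinates in ``site_index``.
    """
    if diff.n != summary.n_sites:
        raise ContractError(
            f"pair alignment length {diff.n} != phylogeny n_sites {summary.n_sites}"
        )
    keep = diff.usable.copy()
    if summary.transversion_sites:
        tv_idx = np.fromiter(summary.transversion_sites, dtype=np.int64) - 1
        keep[tv_idx] = False
    if not np.any(keep):
        raise EstimationError("no sites survive masking; estimation is impossible")
    z = (diff.classification == TRANSITION).astype(np.int8)
    sites = np.nonzero(keep)[0] + 1
    return ParityProblem(
        counts=summary.transition_counts[keep],
        parity=z[keep],
        site_index=sites,
    )


def estimate_distance(problem: ParityProblem, method: str = "conditional",
                      **options) -> DistanceEstimate:
    """Estimate p on a masked problem; thin dispatcher to the estimators."""
    return estimators.estimate(problem, method=method, **options)


def bootstrap_sd(problem: ParityProblem, method: str = "conditional",
                 B: int = 100, seed=None, **options) -> float:
    """Bootstrap standard deviation of p_hat by resampling sites.

    Site indices are drawn with replacement, jointly for X and Z, the
    estimator is re-run on each resample, and the SD of the B estimates is
    returned.  More than 20% failed resamples aborts with an error.
    """
    if B < 2:
        raise ContractError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = problem.n
    estimates = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = ParityProblem(problem.counts[idx], problem.parity[idx])
        try:
            estimates.append(estimate_distance(sub, method=method, **options).p_hat)
        except (EstimationError, ContractError):
            failures += 1
    if failures > 0.2 * B:
        raise EstimationError(f"bootstrap failed on {failures}/{B} resamples")
    return float(np.std(estimates, ddof=1))


def calibrate(p_hat: float, cfg: CalibrationConfig) -> float:
    """Convert a scaled distance to years via the total tree length.

    The total phylogeny edge length in years is the mean number of
    substitutions per site over the tree divided by the per-site per-year
    rate mu; p_hat is a fraction of that length.
    """
    if p_hat < 0:
        raise ContractError("p_hat must be non-negative")
    return p_hat * cfg.tree_length_years


def tmrca(p_years: float, cfg: CalibrationConfig) -> float:
    """TMRCA in years: (age_1 + age_2 + p_years) / 2.

    The calibrated distance spans both lineages from their common
    ancestor down to each (possibly ancient) sample, so the ancestor sits
    half the total path above the mean sampling time.
    """
    if p_years < 0:
        raise ContractError("p_years must be non-negative")
    return 0.5 * (cfg.sample_age_1 + cfg.sample_age_2 + p_years)


def aggregate_tmrca(estimates) -> float:
    """Uniform average of per-pair TMRCAs over many modern sequences.

    Weighted averaging (down-weighting near-duplicate modern sequences)
    is deliberately out of scope: for panels of diverse origins the
    uniform mean is an adequate approximation.
    """
    values = list(estimates)
    if not values:
        raise ContractError("cannot aggregate an empty list of TMRCAs")
    return float(np.mean(values))
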