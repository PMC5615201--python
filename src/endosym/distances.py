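"""Model-corrected nucleotide distances and the two-lineage relative rate test.

The relative rate test asks whether two lineages (e.g. an endosymbiont and
its free-living relatives) have accumulated substitutions at the same rate
since their common ancestor, using an outgroup to locate that ancestor on
the path between them. For a triplet (a in lineage 1, b in lineage 2,
o in outgroup) with corrected pairwise distances d_ab, d_ao, d_bo:

    K1 = (d_ab + d_ao - d_bo) / 2      distance from lineage 1 to the ancestor
    K2 = (d_ab + d_bo - d_ao) / 2      distance from lineage 2 to the ancestor

so K1 + K2 = d_ab exactly. Under equal rates E[K1 - K2] = 0; the test
statistic is z = (K1 - K2) / SE, with the standard error estimated by a
nonparametric bootstrap over alignment columns, and a two-sided normal
P value. A K1/K2 ratio below 1 means lineage 1 evolves more slowly.

Distances are corrected with the Kimura 2-parameter model by default
(transitions P and transversions Q treated separately), or Jukes-Cantor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .composition import SequenceRecord

__all__ = [
    "Alignment",
    "SiteFilterPolicy",
    "DistanceMatrix",
    "RateTestResult",
    "SaturationError",
    "filter_sites",
    "p_q_counts",
    "jc69_distance",
    "k2p_distance",
    "triplet_decompose",
    "distance_matrix",
    "relative_rate_test",
]

# Base codes: A=0, C=1, G=2, T=3 (U folded into T); ambiguity codes -1,
# gap characters -2. Any negative code is missing for pairwise counting.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "-": -2, ".": -2}
AMBIGUOUS = -1
GAP = -2
_DECODE = "ACGT"


class SaturationError(ValueError):
    """Distance correction undefined: observed divergence at or past saturation."""


@dataclass(frozen=True)
class Alignment:
    """A gap-aware multiple sequence alignment over {A, C, G, T, missing}.

    ``codes`` has shape (n_taxa, n_sites), int8; missing data (gaps and
    ambiguity codes) is -1.
    """

    labels: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        if codes.ndim != 2:
            raise ValueError("codes must be 2-D (taxa x sites)")
        if len(self.labels) != codes.shape[0]:
            raise ValueError("one label per row required")
        if codes.shape[0] < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "codes", codes)

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "Alignment":
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        codes = np.full((len(records), lengths.pop()), AMBIGUOUS, dtype=np.int8)
        for i, rec in enumerate(records):
            codes[i] = [_CODE.get(ch, AMBIGUOUS) for ch in rec.residues]
        return cls(labels=tuple(r.id for r in records), codes=codes)

    def to_records(self) -> list[SequenceRecord]:
        out = []
        for label, row in zip(self.labels, self.codes):
            residues = "".join(
                _DECODE[c] if c >= 0 else ("N" if c == AMBIGUOUS else "-")
                for c in row
            )
            out.append(SequenceRecord(id=label, residues=residues))
        return out

    def row(self, label: str) -> np.ndarray:
        try:
            return self.codes[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"taxon {label!r} not in alignment") from None


@dataclass(frozen=True)
class SiteFilterPolicy:
    """Column-deletion policy for distance computation.

    ``complete_deletion`` drops every column with missing data in any row;
    ``pairwise_deletion`` keeps all columns and drops sites per pair.
    With ``treat_ambiguous_as_missing`` (default) ambiguity codes behave
    like gaps; without it they survive filtering but are still excluded
    from pairwise counts, which can only score unambiguous bases.
    """

    mode: str = "complete_deletion"
    treat_ambiguous_as_missing: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("complete_deletion", "pairwise_deletion"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of corrected distances (substitutions per site)."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=np.float64)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and nonnegative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "d", d)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


@dataclass(frozen=True)
class RateTestResult:
    """Relative-rate-test output: lineage distances to the common ancestor.

    ``negative_k`` flags triplets whose decomposition produced a negative
    K (possible with noisy distances); values are reported unclamped.
    """

    k1: float
    k2: float
    diff: float
    ratio: float
    se_diff: float
    z: float
    p_two_sided: float
    n_sites: int
    n_bootstrap: int
    seed: int | None
    negative_k: bool = False


def filter_sites(aln: Alignment, policy: SiteFilterPolicy | None = None) -> Alignment:
    """Apply the column-deletion policy; returns a (possibly) narrower alignment."""
    policy = policy or SiteFilterPolicy()
    if policy.mode == "pairwise_deletion":
        # All-missing columns are uninformative under any policy.
        keep = ~np.all(aln.codes < 0, axis=0)
    else:
        if policy.treat_ambiguous_as_missing:
            keep = np.all(aln.codes >= 0, axis=0)
        else:
            keep = np.all(aln.codes != GAP, axis=0)
    if not keep.any():
        raise ValueError("no columns survive site filtering")
    return Alignment(labels=aln.labels, codes=aln.codes[:, keep])


_TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def p_q_counts(seq_a: np.ndarray, seq_b: np.ndarray) -> tuple[float, float, int]:
    """Transition and transversion fractions between two coded sequences.

    Returns (P, Q, n) where n is the number of shared unambiguous sites.
    """
    a = np.asarray(seq_a, dtype=np.int8)
    b = np.asarray(seq_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    shared = (a >= 0) & (b >= 0)
    n = int(shared.sum())
    if n == 0:
        raise ValueError("no shared unambiguous sites between sequences")
    a, b = a[shared], b[shared]
    diff = a != b
    # Transitions are purine<->purine or pyrimidine<->pyrimidine: codes with
    # equal parity (A=0/G=2, C=1/T=3) differ by 2.
    transitions = diff & (((a ^ b) & 1) == 0)
    n_ts = int(transitions.sum())
    n_tv = int(diff.sum()) - n_ts
    return n_ts / n, n_tv / n, n


def jc69_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) for mismatch fraction p."""
    if p < 0:
        raise ValueError("mismatch fraction must be nonnegative")
    if p >= 0.75:
        raise SaturationError(
            f"mismatch fraction {p} at or beyond JC69 saturation (0.75)"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p_distance(P: float, Q: float) -> float:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be nonnegative")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution fractions P={P}, Q={Q} at or beyond K2P saturation"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _pair_distance(seq_a: np.ndarray, seq_b: np.ndarray, model: str) -> float:
    P, Q, _ = p_q_counts(seq_a, seq_b)
    if model == "jc69":
        return jc69_distance(P + Q)
    if model == "k2p":
        return k2p_distance(P, Q)
    raise ValueError(f"unknown model {model!r}")


def triplet_decompose(d_ab: float, d_ao: float, d_bo: float) -> tuple[float, float]:
    """Split d_ab into lineage-specific distances to the common ancestor.

    K1 + K2 = d_ab holds exactly. Negative values (noisy distances) are
    returned as-is; callers decide how to flag them.
    """
    for name, v in (("d_ab", d_ab), ("d_ao", d_ao), ("d_bo", d_bo)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and nonnegative, got {v}")
    k1 = (d_ab + d_ao - d_bo) / 2.0
    k2 = (d_ab + d_bo - d_ao) / 2.0
    return k1, k2


def distance_matrix(
    aln: Alignment,
    model: str = "k2p",
    policy: SiteFilterPolicy | None = None,
) -> DistanceMatrix:
    """All-pairs corrected distances under complete or pairwise deletion."""
    policy = policy or SiteFilterPolicy()
    filtered = filter_sites(aln, policy)
    n = filtered.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(
                filtered.codes[i], filtered.codes[j], model
            )
    return DistanceMatrix(labels=filtered.labels, d=d)


def _pattern_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse alignment columns to unique site patterns with multiplicities."""
    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    return patterns, counts


def _pair_pq_from_patterns(
    patterns: np.ndarray, counts: np.ndarray, i: int, j: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pattern indicator vectors (ts, tv, shared) for taxon rows i, j."""
    a, b = patterns[:, i], patterns[:, j]
    shared = (a >= 0) & (b >= 0)
    diff = shared & (a != b)
    ts = diff & (((a ^ b) & 1) == 0)
    tv = diff & ~ts
    return ts.astype(float), tv.astype(float), shared.astype(float)


def _triplet_diffs(
    pair_counts: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]],
    triplets: list[tuple[int, int, int]],
    model: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean K1 and K2 across triplets for vectorized bootstrap replicates.

    ``pair_counts`` maps (i, j) to (n_ts, n_tv, n_shared) arrays of shape
    (n_replicates,). Returns (K1_mean, K2_mean) arrays, NaN where any
    distance saturates.
    """

    def dist(i: int, j: int) -> np.ndarray:
        key = (min(i, j), max(i, j))
        n_ts, n_tv, n_sh = pair_counts[key]
        with np.errstate(divide="ignore", invalid="ignore"):
            P = n_ts / n_sh
            Q = n_tv / n_sh
            if model == "jc69":
                arg = 1.0 - 4.0 * (P + Q) / 3.0
                d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.nan)
            else:
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                ok = (w1 > 0) & (w2 > 0)
                d = np.where(
                    ok,
                    -0.5 * np.log(np.maximum(w1, 1e-300))
                    - 0.25 * np.log(np.maximum(w2, 1e-300)),
                    np.nan,
                )
        return d

    k1_sum = 0.0
    k2_sum = 0.0
    for a, b, o in triplets:
        d_ab, d_ao, d_bo = dist(a, b), dist(a, o), dist(b, o)
        k1_sum = k1_sum + (d_ab + d_ao - d_bo) / 2.0
        k2_sum = k2_sum + (d_ab + d_bo - d_ao) / 2.0
    return k1_sum / len(triplets), k2_sum / len(triplets)


def relative_rate_test(
    aln: Alignment,
    lineage1: Iterable[str],
    lineage2: Iterable[str],
    outgroup: Iterable[str],
    model: str = "k2p",
    n_bootstrap: int = 2000,
    seed: int | None = None,
    policy: SiteFilterPolicy | None = None,
) -> RateTestResult:
    """Two-lineage relative rate test with column-bootstrap standard error.

    For every triplet (a in lineage1, b in lineage2, o in outgroup) the
    corrected distances are decomposed into per-lineage distances K1, K2 to
    the common ancestor; K1 and K2 are unweighted means over triplets. The
    standard error of K1 - K2 comes from resampling alignment columns with
    replacement ``n_bootstrap`` times (implemented as multinomial
    resampling of site-pattern counts, which is equivalent because the
    statistic depends on columns only through their counts).
    """
    l1, l2, og = list(lineage1), list(lineage2), list(outgroup)
    if not l1 or not l2 or not og:
        raise ValueError("lineage1, lineage2 and outgroup must be nonempty")
    if set(l1) & set(l2) or set(l1) & set(og) or set(l2) & set(og):
        raise ValueError("lineage and outgroup taxon sets must be disjoint")
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be at least 2")
    if model not in ("jc69", "k2p"):
        raise ValueError(f"unknown model {model!r}")

    filtered = filter_sites(aln, policy or SiteFilterPolicy())
    idx = {lab: i for i, lab in enumerate(filtered.labels)}
    try:
        l1_i = [idx[t] for t in l1]
        l2_i = [idx[t] for t in l2]
        og_i = [idx[t] for t in og]
    except KeyError as exc:
        raise KeyError(f"taxon {exc.args[0]!r} not in alignment") from None

    triplets = [(a, b, o) for a in l1_i for b in l2_i for o in og_i]
    pairs = sorted(
        {(min(i, j), max(i, j)) for a, b, o in triplets for i, j in ((a, b), (a, o), (b, o))}
    )

    patterns, counts = _pattern_counts(filtered.codes)
    n_sites = filtered.n_sites
    indicators = {
        pair: _pair_pq_from_patterns(patterns, counts, *pair) for pair in pairs
    }

    # Observed statistic from the full pattern counts.
    obs = {
        pair: (
            np.array([ind[0] @ counts]),
            np.array([ind[1] @ counts]),
            np.array([ind[2] @ counts]),
        )
        for pair, ind in indicators.items()
    }
    k1_obs, k2_obs = _triplet_diffs(obs, triplets, model)
    k1, k2 = float(k1_obs[0]), float(k2_obs[0])
    if math.isnan(k1) or math.isnan(k2):
        raise SaturationError("observed distances saturated; rate test undefined")
    diff = k1 - k2

    # Column bootstrap via multinomial pattern-count resampling.
    rng = np.random.default_rng(seed)
    boot_counts = rng.multinomial(n_sites, counts / n_sites, size=n_bootstrap)
    boot = {
        pair: (boot_counts @ ind[0], boot_counts @ ind[1], boot_counts @ ind[2])
        for pair, ind in indicators.items()
    }
    k1_b, k2_b = _triplet_diffs(boot, triplets, model)
    diffs = k1_b - k2_b
    valid = np.isfinite(diffs)
    n_valid = int(valid.sum())
    if n_valid < n_bootstrap:
        warnings.warn(
            f"{n_bootstrap - n_valid} of {n_bootstrap} bootstrap replicates "
            "saturated and were dropped",
            RuntimeWarning,
        )
    if n_valid < 2:
        raise SaturationError("too few valid bootstrap replicates")
    se = float(np.std(diffs[valid], ddof=1))

    if se == 0.0:
        z = 0.0 if diff == 0.0 else math.inf * math.copysign(1.0, diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / se
        p = float(2.0 * stats.norm.sf(abs(z)))

    return RateTestResult(
        k1=k1,
        k2=k2,
        diff=diff,
        ratio=k1 / k2 if k2 != 0 else (1.0 if k1 == 0 else math.inf),
        se_diff=se,
        z=z,
        p_two_sided=p,
        n_sites=n_sites,
        n_bootstrap=n_bootstrap,
        seed=seed,
        negative_k=(k1 < 0 or k2 < 0),
    )
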