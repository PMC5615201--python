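"""Seeded synthetic inputs with known ground truth.

Four generators stand in for the study's raw material so every downstream
stage is testable without photographs or database downloads:

* ``generate_cuticle_image`` — a ventral-cuticle photograph model: a base
  body color plus per-channel Gaussian sensor noise, with a stated fraction
  of pixels replaced by specular highlights and shadows. The analytic
  redness of the base color is returned as ground truth.
* ``simulate_alignment`` — sequences evolved site-independently down a
  rooted tree under JC69 or K2P using exact closed-form transition
  probabilities (no Gillespie steps), from a uniform-composition root.
  Branch lengths are expected substitutions per site, so lineage-rate
  asymmetry is expressed directly in the tree.
* ``generate_composition_sequences`` — i.i.d. sites from a fixed base
  frequency vector, for AT-content estimation tests.
* ``generate_weights`` — two-group Gaussian body-weight samples truncated
  at zero (negative draws are rejected and redrawn).

All generators are deterministic given their seed. A pipeline-level seed
can be split into per-stage substreams with :func:`stage_seeds`, which
spawns ``numpy.random.SeedSequence(seed)`` children in the fixed order
images, alignments, composition, weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .composition import SequenceRecord
from .distances import Alignment
from .imaging import RGBImage

__all__ = [
    "ImageSimParams",
    "SeqSimParams",
    "CompositionSimParams",
    "stage_seeds",
    "generate_cuticle_image",
    "simulate_alignment",
    "generate_composition_sequences",
    "generate_weights",
]

_STAGES = ("images", "alignments", "composition", "weights")


def stage_seeds(seed: int) -> dict[str, int]:
    """Split one top-level seed into documented per-stage substream seeds."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for name, child in zip(_STAGES, children)
    }


def _check_rgb(name: str, rgb) -> tuple[int, int, int]:
    r, g, b = rgb
    for v in (r, g, b):
        if not (0 <= v <= 255):
            raise ValueError(f"{name} components must lie in [0, 255], got {rgb}")
    return int(r), int(g), int(b)


@dataclass(frozen=True)
class ImageSimParams:
    """Cuticle-photograph model parameters (body color, noise, highlight/shadow)."""

    width: int
    height: int
    base_rgb: tuple[int, int, int]
    noise_sd: float = 0.0
    highlight_frac: float = 0.0
    shadow_frac: float = 0.0
    highlight_rgb: tuple[int, int, int] = (250, 250, 250)
    shadow_rgb: tuple[int, int, int] = (5, 5, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.highlight_frac < 0 or self.shadow_frac < 0:
            raise ValueError("highlight/shadow fractions must be nonnegative")
        if self.highlight_frac + self.shadow_frac >= 1:
            raise ValueError("highlight_frac + shadow_frac must be < 1")
        for name in ("base_rgb", "highlight_rgb", "shadow_rgb"):
            _check_rgb(name, getattr(self, name))


@dataclass(frozen=True)
class SeqSimParams:
    """Tree-based sequence-evolution parameters.

    ``tree`` is a rooted Newick string whose branch lengths are expected
    substitutions per site; ``model`` is "jc69" or "k2p"; ``kappa`` is the
    K2P transition/transversion rate ratio.
    """

    tree: str
    length: int
    model: str = "jc69"
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.model not in ("jc69", "k2p"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class CompositionSimParams:
    """i.i.d. composition-biased sequence parameters (A, C, G, T frequencies)."""

    base_freqs: tuple[float, float, float, float]
    length: int
    n_sequences: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = self.base_freqs
        if len(freqs) != 4 or any(f < 0 for f in freqs):
            raise ValueError("base_freqs must be four nonnegative values")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1 within 1e-9")
        if self.length < 1 or self.n_sequences < 1:
            raise ValueError("length and n_sequences must be >= 1")


def generate_cuticle_image(params: ImageSimParams) -> tuple[RGBImage, float]:
    """Simulate a cuticle photograph; returns (image, ground-truth redness).

    Each pixel is independently a highlight (probability ``highlight_frac``),
    a shadow (``shadow_frac``), or body: ``base_rgb`` plus independent
    Gaussian noise per channel, rounded and clipped to [0, 255]. The ground
    truth is the analytic redness of the base color,
    R - (R + G + B) / 3.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    u = rng.random((h, w))
    base = np.array(params.base_rgb, dtype=np.float64)
    img = base + rng.normal(0.0, params.noise_sd, size=(h, w, 3)) if params.noise_sd > 0 else np.broadcast_to(base, (h, w, 3)).copy()
    img = np.rint(np.clip(img, 0, 255))
    highlight = u < params.highlight_frac
    shadow = (u >= params.highlight_frac) & (
        u < params.highlight_frac + params.shadow_frac
    )
    img[highlight] = params.highlight_rgb
    img[shadow] = params.shadow_rgb
    r, g, b = params.base_rgb
    truth = r - (r + g + b) / 3.0
    return RGBImage(img.astype(np.uint8)), truth


def _transition_matrix(d: float, model: str, kappa: float) -> np.ndarray:
    """Exact 4x4 substitution probability matrix for branch length d.

    Base order A, C, G, T; transitions are A<->G and C<->T. JC69 is K2P
    with kappa = 1. d is the expected number of substitutions per site.
    """
    if d < 0:
        raise ValueError(f"negative branch length {d}")
    k = 1.0 if model == "jc69" else kappa
    e1 = math.exp(-4.0 * d / (k + 2.0))
    e2 = math.exp(-2.0 * d * (k + 1.0) / (k + 2.0))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = P[1, 3] = P[3, 1] = p_ts
    return P


def _evolve(parent: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample child states site-by-site given parent states and matrix P."""
    cum = np.cumsum(P[parent], axis=1)
    u = rng.random(parent.size)
    child = (u[:, None] > cum).sum(axis=1)
    return np.minimum(child, 3).astype(np.int8)


def simulate_alignment(params: SeqSimParams) -> Alignment:
    """Evolve a gapless alignment down the tree; one row per leaf."""
    tree = dendropy.Tree.get(data=params.tree, schema="newick")
    rng = np.random.default_rng(params.seed)
    root_state = rng.integers(0, 4, size=params.length, dtype=np.int8)
    states: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_state}
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = root_state
        else:
            d = node.edge.length if node.edge.length is not None else 0.0
            if d < 0:
                raise ValueError(f"negative branch length {d}")
            P = _transition_matrix(float(d), params.model, params.kappa)
            state = _evolve(states[node.parent_node], P, rng)
            states[node] = state
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("every leaf must be labeled")
            labels.append(node.taxon.label)
            rows.append(state)
    return Alignment(labels=tuple(labels), codes=np.vstack(rows))


def generate_composition_sequences(
    params: CompositionSimParams,
) -> list[SequenceRecord]:
    """Draw i.i.d. sequences from fixed base frequencies (A, C, G, T order)."""
    rng = np.random.default_rng(params.seed)
    bases = np.array(list("ACGT"))
    out = []
    for i in range(params.n_sequences):
        draws = rng.choice(4, size=params.length, p=np.asarray(params.base_freqs))
        out.append(
            SequenceRecord(id=f"sim_{i + 1}", residues="".join(bases[draws]))
        )
    return out


def generate_weights(
    n: int, mean: float, sd: float, seed: int | None = None
) -> np.ndarray:
    """n Gaussian body-weight draws (mg), truncated at 0 by rejection."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out = rng.normal(mean, sd, size=n)
    while True:
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, size=int(neg.sum()))
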