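"""Two-sample phenotype comparisons and pipeline orchestration.

Symbiotic vs. aposymbiotic cohorts are compared on cuticle redness and dry
body weight with a two-sided Welch (unequal-variance) t test by default;
Student's pooled-variance test is selectable. Significance codes follow the
conventional star scale: ns (P >= 0.05), * (P < 0.05), ** (P < 0.01),
*** (P < 0.001). Two planned comparisons are made and no multiple-testing
correction is applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "PipelineConfig",
    "welch_t_test",
    "significance_code",
    "compare_phenotypes",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_sided: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int


def welch_t_test(x: Sequence[float], y: Sequence[float], pooled: bool = False) -> TTestResult:
    """Two-sided two-sample t test; Welch by default, Student's if ``pooled``.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny) with Welch-Satterthwaite
    degrees of freedom. If both samples have zero variance and equal means,
    p = 1 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    nx, ny = x.size, y.size
    mx, my = float(x.mean()), float(y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    if vx == 0.0 and vy == 0.0:
        t = 0.0 if mx == my else math.copysign(math.inf, mx - my)
        p = 1.0 if mx == my else 0.0
        df = float(nx + ny - 2)
    elif pooled:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        df = float(nx + ny - 2)
        t = (mx - my) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        p = float(2.0 * sps.t.sf(abs(t), df))
    else:
        se2 = vx / nx + vy / ny
        t = (mx - my) / math.sqrt(se2)
        df = se2**2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(
        t=float(t),
        df=float(df),
        p_two_sided=p,
        mean_x=mx,
        mean_y=my,
        sd_x=math.sqrt(vx),
        sd_y=math.sqrt(vy),
        n_x=int(nx),
        n_y=int(ny),
    )


def significance_code(p: float) -> str:
    """Star code, monotone in p: *** < 0.001, ** < 0.01, * < 0.05, else ns."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_phenotypes(
    group_a: Sequence[float],
    group_b: Sequence[float],
    label_a: str = "group_a",
    label_b: str = "group_b",
    pooled: bool = False,
) -> dict:
    """One report row comparing two phenotype samples (redness or weight)."""
    res = welch_t_test(group_a, group_b, pooled=pooled)
    return {
        "group_a": label_a,
        "group_b": label_b,
        "n_a": res.n_x,
        "n_b": res.n_y,
        "mean_a": res.mean_x,
        "mean_b": res.mean_y,
        "sd_a": res.sd_x,
        "sd_b": res.sd_y,
        "t": res.t,
        "df": res.df,
        "p_two_sided": res.p_two_sided,
        "significance": significance_code(res.p_two_sided),
    }


@dataclass
class PipelineConfig:
    """Declarative pipeline run: stages, inputs, parameters, seed, outputs.

    ``stages`` execute in the order given; recognized names are
    ``simulate``, ``redness``, ``atcontent``, ``rrt``, ``nj`` and
    ``report``. Stage parameters live in the correspondingly named dicts.
    """

    stages: list[str]
    out_dir: str
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    redness: dict = field(default_factory=dict)
    atcontent: dict = field(default_factory=dict)
    rrt: dict = field(default_factory=dict)
    nj: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written).

    Every output file is listed in the manifest with a SHA-256 digest, so a
    re-run with the same config and seed can be verified bit-for-bit.
    """
    from . import __version__
    from . import composition as comp
    from . import distances as dst
    from . import imaging as img
    from . import phylogeny as phy
    from . import simulate as sim

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = sim.stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
        "outputs": {},
        "inputs": {},
    }

    def record_output(path: Path) -> None:
        manifest["outputs"][str(path)] = _sha256(path)

    def record_input(stage: str, path: str | Path) -> Path:
        p = Path(path)
        if not p.exists():
            raise PipelineError(f"stage {stage!r}: input path {p} does not exist")
        manifest["inputs"][str(p)] = _sha256(p)
        return p

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                cfg = config.simulate
                if "image" in cfg:
                    params = sim.ImageSimParams(seed=seeds["images"], **cfg["image"])
                    image, truth = sim.generate_cuticle_image(params)
                    path = out_dir / "simulated_cuticle.png"
                    img.write_image(image, path)
                    record_output(path)
                    manifest.setdefault("ground_truth", {})["redness"] = truth
                if "alignment" in cfg:
                    params = sim.SeqSimParams(seed=seeds["alignments"], **cfg["alignment"])
                    aln = sim.simulate_alignment(params)
                    path = out_dir / "simulated_alignment.fasta"
                    comp.write_fasta(aln.to_records(), path)
                    record_output(path)
                if "composition" in cfg:
                    params = sim.CompositionSimParams(
                        seed=seeds["composition"], **cfg["composition"]
                    )
                    recs = sim.generate_composition_sequences(params)
                    path = out_dir / "simulated_composition.fasta"
                    comp.write_fasta(recs, path)
                    record_output(path)
                if "weights" in cfg:
                    rows = []
                    rng_seed = seeds["weights"]
                    for k, grp in enumerate(cfg["weights"]):
                        w = sim.generate_weights(
                            grp["n"], grp["mean"], grp["sd"], seed=rng_seed + k
                        )
                        rows.extend(
                            {"group": grp.get("label", f"group{k}"), "weight_mg": v}
                            for v in w
                        )
                    path = out_dir / "simulated_weights.tsv"
                    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                    record_output(path)
            elif stage == "redness":
                rows = []
                for item in config.redness.get("images", []):
                    path = record_input(stage, item["path"])
                    image = img.read_image(path)
                    rect = tuple(item["rect"])
                    res = img.score_image(
                        image,
                        rect,
                        low_frac=config.redness.get("low_frac", 0.10),
                        high_frac=config.redness.get("high_frac", 0.10),
                    )
                    rows.append(
                        {
                            "image": path.name,
                            "n_total": res.n_pixels_total,
                            "n_used": res.n_pixels_used,
                            "redness_index": res.index,
                        }
                    )
                out = out_dir / "redness.tsv"
                pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
                record_output(out)
            elif stage == "atcontent":
                path = record_input(stage, config.atcontent["fasta"])
                rows = []
                for rec in comp.read_fasta(path):
                    s = comp.at_content(rec)
                    rows.append(
                        {
                            "id": rec.id,
                            "length": s.length_ungapped,
                            "A": s.a,
                            "C": s.c,
                            "G": s.g,
                            "T": s.t,
                            "ambiguous": s.ambiguous_count,
                            "at_percent": s.at_content,
                        }
                    )
                out = out_dir / "atcontent.tsv"
                pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
                record_output(out)
            elif stage == "rrt":
                cfg = config.rrt
                path = record_input(stage, cfg["fasta"])
                aln = dst.Alignment.from_records(comp.read_fasta(path))
                res = dst.relative_rate_test(
                    aln,
                    cfg["lineage1"],
                    cfg["lineage2"],
                    cfg["outgroup"],
                    model=cfg.get("model", "k2p"),
                    n_bootstrap=cfg.get("n_bootstrap", 2000),
                    seed=seeds["alignments"],
                )
                out = out_dir / "relative_rate_test.tsv"
                pd.DataFrame([asdict(res)]).to_csv(out, sep="\t", index=False)
                record_output(out)
            elif stage == "nj":
                cfg = config.nj
                path = record_input(stage, cfg["fasta"])
                aln = dst.Alignment.from_records(comp.read_fasta(path))
                tree = phy.bootstrap_nj(
                    aln,
                    model=cfg.get("model", "k2p"),
                    n_reps=cfg.get("n_reps", 1000),
                    seed=seeds["alignments"],
                )
                out = out_dir / "nj_tree.nwk"
                out.write_text(phy.write_newick(tree))
                record_output(out)
            elif stage == "report":
                rows = []
                for cmp_cfg in config.report.get("comparisons", []):
                    path = record_input(stage, cmp_cfg["table"])
                    df = pd.read_csv(path, sep="\t")
                    col = cmp_cfg["value_column"]
                    ga = df[df[cmp_cfg["group_column"]] == cmp_cfg["group_a"]][col]
                    gb = df[df[cmp_cfg["group_column"]] == cmp_cfg["group_b"]][col]
                    rows.append(
                        compare_phenotypes(
                            ga.to_numpy(),
                            gb.to_numpy(),
                            label_a=cmp_cfg["group_a"],
                            label_b=cmp_cfg["group_b"],
                        )
                    )
                out = out_dir / "phenotype_report.tsv"
                pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
                record_output(out)
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": stage, "seconds": round(time.perf_counter() - t0, 4)}
        )
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
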