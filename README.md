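# endosym

Analysis toolkit for insect endosymbiont studies that pair a **host
phenotype readout** (cuticle pigmentation from RGB photographs) with a
**symbiont molecular-evolution readout** (16S rRNA composition, corrected
distances, relative rate tests, and neighbor-joining phylogenies). It is
aimed at entomologists and microbial ecologists comparing symbiotic and
aposymbiotic (symbiont-cured) insect lines, where symbiont loss shows up as
a subtly redder, less sclerotized cuticle, and where the symbiont's genome
shows the classic signatures of reductive evolution: AT-biased composition
and an accelerated — or, relative to other endosymbionts, decelerated —
substitution rate.

## What it computes

**Cuticle redness.** From a ventral photograph and a user-supplied
rectangle bounding the metasternum, the maximal inscribed square is
extracted; pixels whose brightness (mean of R, G, B) ranks in the top 10%
or bottom 10% are masked to suppress specular highlights and shadows; the
remaining *n* pixels are scored by

    redness index = Σ [ R − mean(R, G, B) ] / n

A grayscale patch scores exactly 0, pure red scores 170, and the index is
invariant to uniform exposure shifts.

**Molecular evolution.** Pairwise distances are corrected with the Kimura
2-parameter model, d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with transitions
P and transversions Q counted separately (Jukes–Cantor selectable). The
two-lineage relative rate test decomposes each triplet (lineage 1 taxon a,
lineage 2 taxon b, outgroup o) as

    K1 = (d_ab + d_ao − d_bo) / 2,    K2 = (d_ab + d_bo − d_ao) / 2

so K1 + K2 = d_ab exactly; the standard error of K1 − K2 comes from a
column bootstrap and the P value from a two-sided normal test. Trees are
built by Saitou–Nei neighbor joining with bootstrap bipartition supports
and serialized as Newick. AT content is 100·(A+T)/(A+C+G+T) over
unambiguous bases.

**Synthetic data.** Seeded generators produce cuticle photographs (base
color + Gaussian noise + highlight/shadow pixels), alignments evolved under
JC69/K2P with per-branch expected substitutions, composition-biased i.i.d.
sequences, and two-group body-weight samples — each with known ground
truth, so the whole pipeline is testable without photographs or database
downloads.

## Worked example

```python
import endosym as es

# Synthetic cuticle photograph: body color (150,100,100), sensor noise
# sd 8, 5% specular highlights, 5% shadows.
img, truth = es.generate_cuticle_image(es.ImageSimParams(
    width=200, height=200, base_rgb=(150, 100, 100), noise_sd=8,
    highlight_frac=0.05, shadow_frac=0.05, seed=1))
res = es.score_image(img, rect=(0, 0, 200, 200))
print(f"n_used={res.n_pixels_used} index={res.index:.2f} (truth {truth:.2f})")
# n_used=32298 index=33.35 (truth 33.33)

# A symbiont-like lineage evolving at roughly half the rate of its sister:
# branches 0.06 vs 0.13 substitutions/site, outgroup 0.10, 100 kb.
aln = es.simulate_alignment(es.SeqSimParams(
    tree="((sym:0.06,ref:0.13):0.0,outgroup:0.10);",
    length=100_000, model="k2p", kappa=2.0, seed=1))
r = es.relative_rate_test(aln, ["sym"], ["ref"], ["outgroup"],
                          n_bootstrap=2000, seed=2)
print(f"K1={r.k1:.3f} K2={r.k2:.3f} K1/K2={r.ratio:.2f} P={r.p_two_sided:.2e}")
# K1=0.059 K2=0.130 K1/K2=0.45 P=0.00e+00
```

`n_used` is the pixel count after masking (80.7% of the ROI survives the
10%/10% cuts); the recovered index 33.35 matches the analytic redness of
the base color, 150 − 350/3 = 33.33, so masking removed the injected
highlights and shadows. In the rate test, K1 and K2 recover the simulated
per-lineage branch lengths, the ratio 0.45 the 2-fold rate asymmetry, and
the P value rejects rate equality decisively at this alignment length.

The same stages are scriptable from the shell:

```sh
endosym redness --image cuticle.png --rect 0,0,200,200
endosym atcontent symbiont_16S.fasta
endosym dist aligned.fasta --model k2p
endosym rrt aligned.fasta --l1 sym --l2 ref --og outgroup --boot 2000 --seed 2
endosym nj aligned.fasta --boot 1000 --seed 3
endosym report --config run.json      # multi-stage pipeline with manifest
```

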