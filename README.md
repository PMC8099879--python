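# g4smlm

Quantitative single-molecule analysis of replication-fork-coupled
G-quadruplexes (G4s): a tested, reusable implementation of the
statistics used to mine multi-color single-molecule localization
microscopy (SMLM) data for recurrent replisome/G4 spatial patterns,
together with the smFRET kinetics analysis of G4 folding and
unfolding.  It is aimed at microscopists and computational biologists
who want the full pipeline — raw sCMOS frames to significance-tested
spatial statistics — with every stage driven by seeded synthetic data
carrying known ground truth.

## What it computes

**Localization.**  Raw camera stacks are processed with
inverse-variance-weighted box filtering, per-candidate maximum
likelihood fitting of a pixel-integrated 2D Gaussian PSF under the
per-pixel sCMOS noise model (Poisson shot noise ⊛ Gaussian read
noise), Cramér–Rao lower bound (CRLB) precision estimates, and
merging of blinking events that reappear in consecutive frames within
2.5× the localization precision (inverse-CRLB-variance averaging).

**Registration.**  Channels are mapped onto the reference channel by a
2nd-degree polynomial warp fitted to mutually-nearest fiducial bead
pairs.

**Pair correlation.**  The auto-correlation of one species,

    g(r) = <δρ(R) δρ(R+r)> / <ρ>²   (baseline 1),

is estimated by direct pair counting and fitted by the two-Gaussian
focus model

    g(r) = exp(−r²/4σ²)/(4πσ²⟨ρ⟩) + A·exp(−r²/(4(σ²+r_app²))) + 1,

yielding the localization precision σ, the apparent focus radius
r_app, and the molecular content per focus ⟨N⟩ = 2π⟨ρ⟩A·r_app².
Cross-correlation between two registered channels with a randomized
baseline quantifies colocalization.

**Triple correlation (TC).**  The third-order statistic

    f(r₁, r₂) = <δρ₁(R) δρ₂(R+r₁) δρ₃(R+r₂)> / (⟨ρ₁⟩⟨ρ₂⟩⟨ρ₃⟩)

detects recurrent three-species geometries (e.g. MCM / nascent DNA /
G4).  It is computed by visiting every channel-1 coordinate,
estimating density fluctuations in sector-annulus bins, averaging over
orientation and collapsing onto the rotation-invariant geometry grid
(r₁, r₂, r₃).  Significance is calibrated against CSR-resampled null
maps with exact family-wise control via the null maximum statistic;
the conditional local density C₃ = ⟨δρ₁δρ₂δρ₃⟩/⟨δρ₁δρ₂⟩ reports how
densely the third species populates its vertex of a significant
pattern.

**Cluster colocalization.**  DBSCAN foci (eps 15 nm, min 3 points) and
edge-to-edge nearest-neighbor distances between cluster boundaries;
pairs within 5 nm count as colocalized, against a Monte-Carlo baseline
that rigidly repositions and reorients clusters inside the ROI.

**smFRET kinetics.**  Frame-wise efficiency E = a/(a+d), two-Gaussian
histogram decomposition into folded (E ≈ 0.7) and unfolded (E ≈ 0.25)
populations, two-state hidden-Markov idealization (EM + Viterbi), and
maximum-likelihood single-exponential dwell-time fits giving k_unfold
(from folded-state dwells) and k_fold (from unfolded-state dwells).

A seeded synthetic-data module generates every input — camera frames,
bead fields, multi-channel scenes with planted triplet patterns, and
two-state smFRET movies — so that each estimator is validated by
parameter recovery against known ground truth.

## Worked example

```python
from g4smlm.synthetic import SceneSpec, generate_triplet_scene
from g4smlm.triple_correlation import (
    compute_tc_map, conditional_density, find_tc_triplets, tc_null_maps,
)

spec = SceneSpec(n_triplets=50, triplet_geometry=(100.0, 100.0, 100.0),
                 background_density=(20.0, 20.0, 20.0), seed=7)
(ch1, ch2, ch3), truth = generate_triplet_scene(spec)

tc = compute_tc_map(ch1, ch2, ch3, r_max_nm=300.0, bin_width_nm=20.0)
nulls = tc_null_maps(ch1, ch2, ch3, n_rand=20, seed=204)
triplets = find_tc_triplets(tc, nulls)
top = triplets[0]
c3 = conditional_density(ch1, ch2, ch3, top, tc_map=tc)
print(f"top geometry (r1, r2, r3) = ({top.r1_nm:.0f}, {top.r2_nm:.0f}, "
      f"{top.r3_nm:.0f}) nm, z = {top.z:.1f}, C3 = {c3:.0f} um^-2")
```

This prints

```
top geometry (r1, r2, r3) = (110, 90, 110) nm, z = 71.2, C3 = 836 um^-2
```

— the 50 planted equilateral triplets (side 100 nm, so the true
geometry sits on a 20 nm bin edge) are recovered as the most
significant recurrent pattern within one bin, with a z-score of ~71
against the CSR null and a conditional channel-3 density of ~840
points/µm² at the pattern vertex (versus a global channel-3 density of
~28 points/µm²).

The same pipeline is available from the shell:

```sh
g4smlm simulate --out-dir scene --n-triplets 50 --seed 7
g4smlm tc scene/localizations.csv --out-csv scene/tc.csv --seed 204
g4smlm fret trajectories.csv --out-json rates.json
```

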