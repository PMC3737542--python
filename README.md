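# mirsite

CLIP-data-driven prediction of miRNA binding sites on mRNAs.

Argonaute crosslinking immunoprecipitation (CLIP) experiments pin down
short (~50 nt) RNA fragments that were bound by the miRNA silencing
machinery. `mirsite` turns that kind of evidence into a predictive model:
it scans transcripts for candidate miRNA sites — both canonical seed
matches and energy-stable *seedless* sites — computes the features that
distinguish bound from unbound sites, quantifies each feature's enrichment
among crosslinked sites, and trains a probabilistic classifier that scores
any candidate site on any transcript. It is aimed at computational
biologists who want transcriptome-style site scoring with an explicit,
testable model at every step, plus a synthetic-data module that makes the
whole pipeline verifiable without any downloads.

## The model in brief

**Site discovery.** Candidate sites of a miRNA on a transcript are (a) all
non-overlapping local optima of the intermolecular duplex free energy
ΔG_hybrid with ΔG_hybrid ≤ −15 kcal/mol (nearest-neighbor stacks + linear
loop penalties + initiation, dynamic programming), and (b) all sites with
forced contiguous Watson–Crick pairing of the seed (miRNA nt 2–7, 2–8,
3–8) with no energy threshold. Sites are typed (8mer, 7mer-m8, 7mer-A1,
6mer, offset-6mer, seedless) and redundant overlaps resolved by the seed
hierarchy, ties by lower ΔG_hybrid.

**Features.** For each site: seed class and 3′ supplementary pairing
(nt 12–17); location within its region; flank AU content (5–30 nt
windows); structural accessibility from an exact Boltzmann-ensemble
partition function over a local 200-nt window (site, seed block, flank
blocks); the two-step hybridization energetics

    ΔG_total = ΔG_hybrid + ΔG_disruption,   ΔG_disruption ≥ 0,

where ΔG_disruption is the ensemble cost of opening the target over the
site, plus a nucleation energy ΔG_nucl; and mean PhastCons-style
conservation of the site, seed block and off-seed block.

**Enrichment and classification.** Sites inside a CLIP interval are IP+,
the rest IP−. Per feature bin, enrichment is the odds ratio
[p⁺/(1−p⁺)]/[p⁻/(1−p⁻)]. Enriched features enter a nonlinear logistic
model log[P/(1−P)] = α + Σβ᷈ᵢXᵢ + Σγᵢⱼ XᵢXⱼ, fitted 10 times on the IP+ set
plus equal-sized random IP− subsamples; the averaged probability is the
prediction, evaluated by ROC, Youden's J = TPR − FPR, and top-ranked
precision, with 10-fold intra-dataset and train-A/test-B inter-dataset
validation. See `docs/methods.md` for details and design rationale.

## Worked example

Generate a small synthetic dataset with planted sites, scan it, and
cross-validate the classifier:

```sh
mirsite simulate --seed 7 --outdir demo --n-transcripts 10
mirsite scan --mirnas demo/mirnas.fa --transcripts demo/transcripts.fa \
    --regions demo/regions.tsv --clip demo/clip.tsv \
    --conservation demo/conservation.tsv --out demo/sites.tsv
mirsite enrich --sites demo/sites.tsv --out demo/enrichment.tsv
mirsite cv --sites demo/sites.tsv --seed 17 --out demo/cv.json
```

which prints

```
426 candidate sites -> demo/sites.tsv

N+ = 200, N- = 226
enriched features: au_up_30, au_down_30, up_access_15, down_access_20,
region, seed_type, site_location, site_access, seed_access, dg_hybrid,
dg_disruption, dg_nucl, dg_total, cons_site, cons_seed, cons_offseed

covariates: au_up_30, au_down_30, up_access_15, down_access_20,
site_location, site_access, dg_hybrid, dg_disruption, dg_nucl, dg_total,
cons_site, seed_type
pooled max J = 0.952, AUC = 0.997, mean fold max J = 0.968
```

Reading this: the scan found 426 candidate sites on the 10 transcripts, of
which 200 fall inside CLIP regions (IP+). Enrichment analysis flags the
planted effects — total hybridization energy, accessibility, flank AU,
conservation, seed class — and the cross-validated ensemble separates
bound from unbound sites with a best Youden's J of 0.95 (J = 0 is chance,
1 is perfect) and area under the ROC of 1.00. `demo/sites.tsv` holds one
row per site with every feature; `mirsite train` / `mirsite evaluate`
fit and apply a model across datasets.

The same pipeline is available as a library
(`mirsite.pipeline.build_site_table`, `run_cv`, …) for notebook use, and
`mirsite.synth.generate_dataset` / `generate_feature_table` expose the
synthetic-data generators directly.

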