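# ofmkit

Quantitative tools for studying how budding-yeast cells maintain chromosomes
that lack efficient replication origins.

When several adjacent origins fail to fire, a chromosome acquires a long
inter-origin gap that a single replication fork must traverse before mitosis.
Derivatives of *S. cerevisiae* chromosome III from which the efficient ARS
elements have been deleted (the 5ORIΔ-ΔR fragment and its relatives) are a
genetic model for this situation: mutants that preferentially destabilize the
origin-depleted derivative — but not the isogenic derivative with a full
origin complement (0ORIΔ-ΔR) — define the **Ofm** (originless fragment
maintenance) phenotype.  `ofmkit` implements the quantitative layer of that
analysis for geneticists running (or re-analyzing) such screens:

- **`ofmkit.fluctuation`** — per-division chromosome loss rates from
  parallel-culture (colony isolation) fluctuation assays.  Counts of
  loss-derived cells per culture follow the jackpot-prone Luria–Delbrück
  distribution; the expected loss events per culture *m* are estimated by the
  Lea–Coulson median method (the default; solves *r̃/m − ln m = 1.24*), the
  P0 zero-class method, or a maximum-likelihood fit over the
  Ma–Sandri–Sarkar recursion, with bootstrap confidence intervals.  The
  per-division rate is *μ = m/N* for cultures of *N* cells.
- **`ofmkit.scoring`** — the **Ofm index**: with rates in units of 10⁻⁵ per
  division,
  `index = (rate5_mut − rate5_base) / (rate0_mut − rate0_base)`,
  the number of additional loss events suffered by the gapped derivative per
  additional loss event suffered by the full-origin derivative.  An index
  near 1 means general chromosome instability; a large index means a
  gap-specific maintenance defect.  Includes delta-method error propagation
  and threshold-based calls.  A transcription of the published
  checkpoint-mutant loss-rate table ships with the package.
- **`ofmkit.sectoring`** — a branching-process simulator of red-sector
  formation in *ade2* colonies losing an *ADE2*-marked chromosome, the
  semi-quantitative sector-count → loss-rate calibration, and the
  duplicate-chromoductant decision rules of the screen (Ofm /
  possible-probable / non-Ofm / not-a-hit).
- **`ofmkit.replication`** — a Monte-Carlo simulator of construct replication
  with stochastic origin licensing and firing times, finite fork speed,
  per-kb permanent fork arrest, and dormant-origin rescue; used to compare
  fork-arrest versus slow-fork explanations of construct stability patterns.
- **`ofmkit.synth`** — fully synthetic strain panels and an end-to-end
  virtual screen (sectoring → verdict → fluctuation assay → Ofm index) with
  known ground truth.

## Worked example

Score every strain in the packaged loss-rate table against the wild type:

```sh
$ ofmkit ofm --baseline "Wild Type"
strain	baseline	index	index_sd	rounded_index	call
Wild Type	Wild Type	Not defined		Not defined	indeterminate
sml1Δ	Wild Type	-3.333333333	3.9690158	-3	non-Ofm
rad9 (ofm14)	Wild Type	80.625	23.46105587	81	Ofm
rad9Δ	Wild Type	65.17241379	19.83276516	65	Ofm
rad17Δ	Wild Type	98.88888889	41.28000749	99	Ofm
rad24Δ	Wild Type	85.55555556	39.82318794	86	Ofm
mec1Δ sml1Δ	Wild Type	39.66666667	11.75171645	40	Ofm
mrc1Δ	Wild Type	6.734693878	1.655507066	7	non-Ofm
chk1Δ	Wild Type	33.33333333	18.47587683	33	indeterminate
rad53Δ sml1Δ	Wild Type	4.375	1.667750324	4	non-Ofm
rad53Δ chk1Δ sml1Δ	Wild Type	18.61111111	5.475661159	19	indeterminate
```

Reading one row: the rad17 deletion raises the gapped-derivative loss rate
from 210 to 1100 (×10⁻⁵ per division) but the full-origin derivative only
from 3 to 12, so the index is (1100−210)/(12−3) ≈ 99 — 99 extra losses of the
gapped fragment per extra loss of the control, a strongly gap-specific
defect, called Ofm.  The mrc1 deletion destabilizes both derivatives
(index 7): general instability, not an Ofm mutant.  The wild-type row scored
against itself is undefined by construction.  `index_sd` is the first-order
(delta-method) propagation of the table's rate SDs.

The sectoring calibration that backs the visual screen:

```sh
$ ofmkit sector-sim --mu 0.0021 --mu 0.01 --mu 0.1 --seed 1
mu	median_sectors	class
0.0021	2	wildtype_like
0.01	9	elevated
0.1	70	high
```

i.e. colonies growing at the wild-type gapped-derivative loss rate show a
median of ~2 visible red sectors, a 10⁻² loss rate ~9 sectors, and a 10⁻¹
loss rate dozens — the three anchor patterns used to classify chromoductants
by eye.

Library use mirrors the CLI:

```python
from ofmkit import simulate_assay, estimate_lc_median

assay = simulate_assay(rate=5e-4, culture_size=10_000, n_cultures=50, seed=1)
est = estimate_lc_median(assay)
print(est.m_hat, est.rate_per_division)   # ~5 events/culture, ~5e-4 per division
```

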