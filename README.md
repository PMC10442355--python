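# pniscreen

Pathologist-mimicking screening for **perineural invasion (PNI)** in
pancreatic ductal adenocarcinoma histology.

PNI — tumor encircling or invading a nerve — upstages pancreatic cancer and
is notoriously laborious to find: a single tiny event hidden anywhere in
dozens of H&E slides flips a case from negative to positive, and
inter-pathologist agreement on it is poor. `pniscreen` implements a
*hierarchical contextual* screening strategy: instead of learning PNI
end-to-end from scarce examples, it detects **nerve** and **tumor**
independently as per-pixel confidence maps, then reasons about their spatial
relationship, and finally presents only the most suspicious fields to a
(simulated) pathologist who makes the actual call. The pipeline is:

1. **Segment** — per-class confidence maps `P(tumor), P(nerve) ∈ [0,1]^{H×W}`
   from a trainable pixel classifier (multiscale features + MLP with two
   independent sigmoid heads) or a seeded oracle-noise segmenter for
   pipeline studies.
2. **Post-process** — binarize at a confidence threshold *t* (default 0.5,
   ties included), label connected components (8-connectivity), and discard
   foci smaller than 10,000 px, the dominant false-alarm mode.
3. **Proximity ranking** — for every nerve component *N* and tumor component
   *T*, the exact minimum pixel-center distance
   `d(N,T) = min_{p∈N, q∈T} ‖p−q‖₂` via per-component distance transforms;
   candidates within 100 px are deduplicated and the *k* = 40 closest fields
   per case (20 for tumor-only cases) are presented in ascending *d*.
4. **Simulated review** — a candidate is confirmed as PNI when tumor abuts
   the nerve outside the main tumor body, or, for an intratumoral nerve,
   when tumor covers at least 33% of the nerve circumference (the
   encirclement fraction: boundary pixels of *N* within ε = 3 px of tumor).
5. **Evaluate** — segmentation metrics (IoU, detection rate, false-alarm
   rate) swept over the confidence threshold in both pixel-level and
   object-level interpretations, and case-level study statistics: the pooled
   two-proportion *z*-test `z = (p̂₂−p̂₁)/√(p̂(1−p̂)(1/n₁+1/n₂))` comparing
   report-based with algorithm-assisted PNI positivity, and a Mann-Whitney
   rank-sum test for per-case quantities.

Because no public PNI dataset exists at this scale, the package ships a
first-class synthetic-study generator: seeded H&E-like tiles with wavy nerve
bundles, lobulated malignant gland clusters, benign-gland confounders (which
deliberately never sit near nerves), and planted PNI events with controlled
nerve-tumor distance and encirclement, organized into multi-slide cases
whose slide counts follow the clinical study's distributions (27 ± 9.4
slides per case; 6.1 ± 1.8 for tumor-only cases).

## Worked example

Clinical comparison from the validation study's published case counts
(59 cases; 31 report-positive of which the algorithm missed 1; 18 of the 28
report-negatives newly detected):

```python
from pniscreen.clinical import summary_from_counts

s = summary_from_counts(n_cases=59, report_positive=31,
                        missed_by_algorithm=1, newly_detected=18)
print(f"report-positive:    {s.report_positive}/{s.n_cases} ({100*s.report_positive_rate:.1f}%)")
print(f"algorithm-positive: {s.algorithm_positive}/{s.n_cases} ({100*s.algorithm_positive_rate:.1f}%)")
print(f"sensitivity vs report: {100*s.sensitivity_vs_report:.1f}%")
print(f"two-proportion z = {s.z_statistic:.3f}, p = {s.p_value:.2e}")
```

```
report-positive:    31/59 (52.5%)
algorithm-positive: 48/59 (81.4%)
sensitivity vs report: 96.8%
two-proportion z = -3.327, p = 8.78e-04
```

The algorithm-assisted workflow calls 81.4% of cases positive versus 52.5%
from the original reports, a significant gain (p ≈ 0.00088); 96.8% of the
originally diagnosed cases are re-found.

An end-to-end synthetic screening study — generate cases, corrupt the ground
truth with a noisy segmenter, screen, review, and score:

```python
from pniscreen.pipeline import run_synthetic_study
from pniscreen.segmentation import NoiseModel

out = run_synthetic_study(n_cases=6, prevalence=0.5, seed=4,
                          noise=NoiseModel(miss_rate=0.1, spurious_rate=2.0))
print(f"sensitivity: {out.sensitivity:.2f}  specificity: {out.specificity:.2f}")
for r in out.results:
    print(f"  {r.case_id}: called={r.pni_called} first_positive_rank={r.first_positive_rank}")
```

```
sensitivity: 1.00  specificity: 1.00
  case_000: called=True first_positive_rank=1
  case_001: called=True first_positive_rank=1
  case_002: called=True first_positive_rank=1
  case_003: called=False first_positive_rank=None
  case_004: called=False first_positive_rank=None
  case_005: called=False first_positive_rank=None
```

Every planted event surfaces at rank 1 (it is the only true nerve-tumor
contact in its case), and no negative case is called: the review rule
rejects the near-miss candidates that mere proximity ranking surfaces.

The same workflow is available from the shell:

```bash
pni-screen simulate --cases 4 --seed 7 --out study/
pni-screen segment  --study study/ --out maps/ --segmenter oracle
pni-screen detect   --study study/ --maps maps/ --out detections/
pni-screen clinic   --study study/ --maps maps/ --out clinic/
pni-screen report   --summary clinic/summary.json
```

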