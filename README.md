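# vinecover

Multicriteria ranking of vineyard floor cover-crop candidates with a hybrid
AHP–TOPSIS pipeline, packaged with the Okanagan Valley (British Columbia)
vineyard screening data it was built around.

Choosing a cover crop for an organic vineyard trades off conflicting
criteria: dry biomass production, ground coverage, interference with the
grape fruiting zone, invasiveness risk, pest associations, drought
tolerance, winter hardiness and wheel-traffic tolerance. `vinecover` is for
agronomists and viticulture researchers who want to (a) turn expert
pairwise judgments into defensible criterion weights, (b) rank candidate
species from a field-data decision matrix, and (c) probe how much a ranking
leans on any one criterion.

## Methods

**AHP weights.** Experts compare criteria pairwise on the Saaty 1–9 scale,
giving a positive reciprocal matrix $A$ with $a_{ij} \approx w_i/w_j$. The
priority weights are the principal right eigenvector, $A w = \lambda_{\max}
w$, normalised so $\sum_j w_j = 1$ (computed by power iteration; a dense
eigendecomposition serves as a test oracle). Judgment coherence is gated by
the consistency ratio $CR = CI/RI$ with $CI = (\lambda_{\max} - n)/(n-1)$
and tabulated random indices $RI(n)$; $CR < 0.10$ is accepted.

**TOPSIS ranking.** Given a decision matrix $x_{ij}$ (alternatives ×
criteria), directions (benefit/cost) and weights $w_j$:
$r_{ij} = x_{ij}/\sqrt{\sum_i x_{ij}^2}$, $v_{ij} = w_j r_{ij}$; the
positive/negative ideal solutions take the per-column best/worst $v_{ij}$
(max for benefit, min for cost criteria, and vice versa); Euclidean
separations $d_i^\*$, $d_i^-$ from the two ideals give the relative
closeness $RC_i = d_i^-/(d_i^\* + d_i^-) \in [0,1]$, ranked descending.

## Worked example

```python
>>> import vinecover as vc
>>> pcm = vc.validate_pcm([[1, 3, 5], [1/3, 1, 3], [1/5, 1/3, 1]],
...                       ["invasiveness", "coverage", "biomass"])
>>> vc.derive_weights(pcm).as_dict()
{'invasiveness': 0.63698557..., 'coverage': 0.25828499..., 'biomass': 0.10472943...}
>>> vc.consistency(pcm).cr
0.03702989...
```

CR = 0.037 < 0.10, so the judgments are acceptably consistent and
invasiveness carries ~64% of the weight. Ranking the packaged field data
for one study cell:

```python
>>> key = vc.StudyKey("KOW", "inter_row", "annual")
>>> vc.rank_alternatives(vc.assemble_matrix(key)).to_frame().sort_values("rank").round(3)
                          d_star  d_minus     rc  rank
Berseem clover             0.020    0.312  0.939     1
Field pea + Cereal rye     0.033    0.312  0.905     2
Crimson clover             0.041    0.310  0.884     3
Persian clover             0.055    0.309  0.850     4
Alsike clover              0.059    0.308  0.839     5
Balansa clover             0.061    0.308  0.835     6
Hairy vetch + Cereal rye   0.310    0.038  0.109     7
```

Berseem clover is the best inter-row annual at the KOW site (closeness
0.94 of a possible 1.0); the hairy vetch + cereal rye mixture, despite the
highest biomass, is last because it carries the maximum invasiveness
penalty under a 0.60 invasiveness weight. The command line offers the same
surface: `vinecover weights pcm.csv`, `vinecover rank matrix.csv`,
`vinecover reproduce --site CFF`, `vinecover sensitivity --site KOW
--position inter-row --cycle annual --drop invasiveness_risk`, and
`vinecover simulate pcm|matrix` for synthetic data.

## Analysis scripts

Numbered drivers under `analysis/` re-run the study end to end and write
tables to `results/`:

1. `01_reproduce_rankings.py` — re-ranks all eight site × position ×
   life-cycle cells and compares with the published closeness scores.
2. `02_sensitivity_invasiveness.py` — removes the dominant invasiveness
   criterion (proportional weight renormalization) and reports rank shifts.
3. `03_synthetic_validation.py` — recovery of planted weights from noisy
   comparison matrices and of planted winners from synthetic decision
   matrices.

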