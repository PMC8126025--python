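# File formats

All tables are tab-separated UTF-8 text. Lines starting with `#` before the
header are comments (run metadata such as the simulation seed is recorded
there). Fraction and sample indices are 1-based and ranges are inclusive.

## Quantification matrix (`quant.tsv`)

Long form, one row per measurement.

| column | type | meaning |
|---|---|---|
| `protein_id` | str | protein / gene identifier |
| `sample` | int | fraction index 1–96 (fraction level) or pooled sample 1–48 |
| `replicate` | int | biological replicate, 1-based |
| `peak_area` | float ≥ 0 | DIA peak area, arbitrary units |

The (protein, sample, replicate) key must be unique and the sample axis
contiguous. Absent cells are materialized as 0 on load (DIA exports report
non-detections as absent rows); the fill count is logged. The level is
auto-detected from the sample range (max > 48 → fraction level); an axis
that never exceeds 47 is ambiguous and requires an explicit
`level=` / `--pool-width` choice by the caller.

## OD280 trace (`od280.tsv`)

| column | type |
|---|---|
| `fraction` | int, 1–96, complete and unique |
| `od280` | float, absorbance at 280 nm |

## Marker table (`markers.tsv`)

| column | meaning |
|---|---|
| `protein_id` | marker protein |
| `compartment` | one of `TP`, `ER`, `GA`, `TGN`, `Chl-envelope`, `TLK`, `MT`, `PM` |
| `source` | free-text citation tag |

A protein may appear under exactly one compartment. The packaged curated
set is `src/ffeprof/data/markers_tables.tsv`
(`ffeprof.load_default_markers()`).

## Annotation table

| column | meaning |
|---|---|
| `protein_id` | protein |
| `agi` | A. thaliana accession `At[1-5CM]gNNNNN`, may be empty |
| `hcm` | high-confidence-marker compartment, may be empty |
| `consensus` | consensus-predictor compartment(s), `;`-separated |

The packaged discordant set (PM-annotated proteins with tonoplast-window
profiles) is `src/ffeprof/data/unexpected_pm.tsv`
(`ffeprof.load_unexpected_pm()`).

## TM prediction table

`protein_id` plus one integer count column per program: `hmmtop`, `tmhmm`
(alpha-helix topology), `mcmbb`, `tmbetadisc_rbf` (beta-barrel). Missing
columns or blank cells count as 0; malformed non-numeric cells are
rejected with their line number.

## Ground truth (`ground_truth.tsv`, simulator output)

`protein_id`, `primary`, `secondary` (empty for singletons),
`weight_primary`, `weight_secondary`, `peak_primary`, `peak_secondary`.
Template peak centers and weights are recorded in `#` header comments as
`# peaks: TP = 16.0:0.75,24.0:0.25`.

## Localization report (`localization.tsv`)

One row per protein: `score_<compartment>` (Pearson r, blank when
undefined), `assigned` (compartment or `unassigned`), `margin`,
`n_populations`, `peak_samples`, `population_masses`,
`population_compartments` (`;`-separated, `none` for unmapped peaks),
`dual_flag`, `discordance_flag` (0/1). Column order is fixed.
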