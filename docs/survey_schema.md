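# Survey file schema

Surveys are comma-separated tables, one row per operation, UTF-8, header
required. `regenscore.io.read_survey` detects which of the two schemas a
file follows from its header. Booleans accept yes/no, true/false, 1/0,
y/n, t/f (case-insensitive). `operation_id` must be unique within a
file. Malformed cells are rejected with the row number and column name.

## Cropland

| column | type | notes |
|---|---|---|
| operation_id | text | unique |
| system | text | `cropland_full` (all nine items) or `cropland_corn` |
| synthetic_fertilizer_used | boolean | |
| herbicide_used | boolean | |
| fungicide_used | boolean | blank for `cropland_corn` (not asked) |
| insecticide_used | boolean | treated seed counts as insecticide use |
| tillage_used | boolean | |
| cover_crop_or_resident_vegetation | boolean | planted cover crops or deliberately fostered resident vegetation |
| field_margins_hedgerows | boolean | blank for `cropland_corn` |
| organic_amendments_used | boolean | blank for `cropland_corn` |
| livestock_integrated | boolean | |

For `cropland_full` rows all nine answers must be present; for
`cropland_corn` the three unasked columns must be blank.

## Rangeland

| column | type | notes |
|---|---|---|
| operation_id | text | unique |
| ivermectin_applications_per_year | integer ≥ 0 | |
| ivermectin_applied_during_grazing | boolean | requires ≥ 1 application |
| stocking_density_au_per_ha | real ≥ 0 | animal units per hectare |
| rotation_frequency_days | real > 0, or `inf`/`never` | days between moves |
| rest_period_days | real ≥ 0 | 0 = continuously grazed |

Organic-certification status, farm age and years-in-system are intake
metadata, not score inputs, and are not part of these schemas.
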