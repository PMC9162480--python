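# Survey CSV schema

UTF-8, comma-delimited, one header row, one row per respondent. Empty cells
are missing values; records missing any pipeline field are ineligible
(complete-case analysis). Column names are fixed; a `column_map` argument to
`read_survey` can rename non-canonical headers on the fly.

## Identifier

| column | type | notes |
|---|---|---|
| `respondent_id` | string | unique within a file |

## Characteristics (canonical tokens)

Unicode dashes and `≤`/`≥` are normalized on read; matching is
case-insensitive. The two weekly-hours columns also accept raw numeric
hours, banded on read with left-open, right-closed boundaries.

| column | vocabulary |
|---|---|
| `gender` | Male, Female |
| `age_band` | 20-30, 31-40, 41-55, >55 |
| `marital_status` | Unmarried, Married, Divorced, Widowed |
| `education` | Doctorate, Master, Undergraduate, Junior college, Others |
| `income_band` | <=5000, 5001-10000, 10001-15000, >15000 (RMB/month) |
| `title` | Senior, Associate senior, Intermediate, Junior, Others |
| `tenure_band` | 1-5, 6-10, 11-15, 16-20, >20 (years) |
| `area` | Eastern, Central, Western |
| `hospital_level` | Tertiary A, Tertiary B, Secondary, First-tier |
| `hospital_nature` | Public general, Public specialized, Private general, Private specialized |
| `department` | Internal, Surgical, Obstetrics and gynecology, Pediatrics, Others |
| `hours_per_week_band` | <=40, 41-60, >60 (or raw hours) |
| `outpatient_hours_band` | <=8, ~16, ~24, ~40, >40 (or raw hours) |
| `health_status` | Very poor, Poor, Fair, Good, Very good |

## Numeric measurements

| column | constraint |
|---|---|
| `months_in_outpatient_clinic` | >= 0; eligibility requires >= 4 |
| `years_employed_current_institution` | >= 0; eligibility requires >= 1 |
| `t_comm`, `t_noncomm` | minutes per visit, >= 0 |
| `n_outpatients_per_day` | count >= 0 |
| `n_admitted_per_day` | count >= 0, <= `n_outpatients_per_day` |
| `satisfaction` | [0, 100] |

## Mental-workload assessments

Two task groups, prefixes `comm_` (physician-patient communication tasks)
and `noncomm_` (paperwork-type tasks). For each group:

- `"{g}_item_01" .. "{g}_item_12"` — item ratings in [0, 100]
  (the instrument administers steps of 10).
- `"{g}_cmp_{A}_{B}"` — 15 pairwise-comparison columns, one per unordered
  pair of dimensions in canonical order MD, PD, TD, PR, FL, Pe; the cell
  holds the winning dimension code, which must be `A` or `B`.

Default item-to-dimension mapping: items 1-2 MD, 3-4 PD, 5-6 TD, 7-8 PR,
9-10 FL, 11-12 Pe (configurable through `ScaleDefinition`).
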