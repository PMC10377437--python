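# Cohort CSV column dictionary (schema version 1)

One row per patient; missing values are empty cells. Dates are integer day
offsets from an arbitrary per-cohort epoch.

| column | type | meaning |
| --- | --- | --- |
| `patient_id` | string | unique within the cohort |
| `age_at_index` | years | age at first HU prescription |
| `sex` | `F`/`M` | |
| `race` | string | e.g. White/Black/Asian/Other |
| `region` | string | e.g. Northeast/Midwest/South/West |
| `te_history` | 0/1 | thromboembolic event history before 6 months post-index |
| `n_phlebotomy` | count | phlebotomy procedures on record |
| `anticoag_antiplatelet` | 0/1 | any anticoagulant/antiplatelet use |
| `smoking`, `alcohol` | 0/1 | |
| `lab_NEP` | % | median neutrophil percentage, 3–6-month window |
| `lab_LYP` | % | median lymphocyte percentage |
| `lab_RDW` | % | median red cell distribution width |
| `lab_WBC` | 10^9/L | median white blood cell count |
| `lab_Hct` | % | median hematocrit |
| `lab_HGB` | g/L | median hemoglobin |
| `lab_Plt` | 10^9/L | median platelet count |
| `obs_BMI` | kg/m² | median body-mass index |
| `obs_DBP`, `obs_SBP` | mmHg | median diastolic / systolic blood pressure |
| `obs_weight` | kg | |
| `obs_height` | cm | |
| `obs_HRT`, `obs_PLS` | bpm | median heart rate / pulse |
| `obs_RSP` | /min | median respiratory rate |
| `index_date` | day | first HU prescription (equals `hu_first`) |
| `hu_first`, `hu_last` | day | HU course bounds (optional) |
| `rux_first`, `rux_last` | day | ruxolitinib course bounds (switchers only) |
| `record_start`, `record_end` | day | EHR record bounds |
| `te_times` | `;`-separated days | strictly increasing TE event days |

Eligibility criteria are supplied separately as YAML
(`pvrisk.cohort.EligibilityCriteria.from_yaml`), with per-patient flags
(`has_mf_et`, `has_other_cytoreductive`, `n_hu_prescriptions`,
`n_rux_prescriptions`) passed alongside the cohort.
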