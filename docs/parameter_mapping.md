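# Parameter mapping

One row per published model input, the field that houses it, and its
role in the canonical model. "Informational" fields are stored and
serialised but do not enter the default (residual-mode) matrices; see
`docs/methods.md`.

## Transition probabilities (per cycle)

| Published input                                         | Field (`transitions.`)      | Base   | Role |
|---------------------------------------------------------|-----------------------------|--------|------|
| Remaining in BPH                                        | `p_bph_stay`                | 0.345  | informational; self-loop is residual (printed mode pins it) |
| BPH patients who experience TURP                        | `p_bph_to_turp`             | 0.021  | used; RRR-scaled in the combination arm |
| BPH patients who experience AUR                         | `p_bph_to_aur`              | 0.004  | used; RRR-scaled in the combination arm |
| AUR patients going through TURP                         | `p_aur_to_turp`             | 0.8    | used; per-episode, survivors' remainder returns to BPH |
| TURP patients' 30-day mortality                         | `p_turp_30day_mortality`    | 0.0237 | used; charged in the procedure cycle |
| TURP patients who recover (=1)                          | — (implied remainder)       | 1      | realised as the post-TURP survivor remainder to recovery |
| TURP patients who require medical intervention          | `p_turp_to_medical`         | 0.059  | used (fraction of survivors) |
| TURP patients who require repeated surgical intervention| `p_turp_to_repeat`          | 0.059  | used (fraction of survivors) |
| Repeated-TURP death from surgical procedure             | `p_repeat_turp_mortality`   | 0      | used (zero surgical risk on the repeat) |
| Patients who remain at recovery state                   | `p_recovery_stay`           | 0.329  | informational (residual rule) |
| Recovered patients who require medical intervention     | `p_recovery_to_medical`     | 0.0467 | used |
| Patients on medication who require the second TURP      | `p_medical_to_second_turp`  | 0.036  | used; blocked after a second procedure |
| Repeated-TURP patients requiring medical intervention   | `p_repeat_to_medical`       | 0.0025 | used (fraction of survivors) |
| Repeated-TURP patients who recover (=1)                 | — (implied remainder)       | 1      | realised as the repeat-TURP survivor remainder to recovery |
| Patients remain on medication                           | `p_medical_stay`            | 0.393  | informational (residual rule) |
| TURP patients who fully recover                         | `p_turp_full_recovery`      | 0.998  | stored, unused (redundant with the survivor remainder) |
| Patients on medication who transition to AUR            | `p_medical_to_aur`          | 0      | used; zero forecloses post-operative AUR |
| All-cause mortality                                     | `life_table`                | —      | calibrated Gompertz stand-in (no published schedule) |

## Treatment effects (4-year relative risk reductions)

| Published input                            | Field               | Base  | Role |
|--------------------------------------------|---------------------|-------|------|
| Efficacy of combination vs monotherapy, AUR | `efficacy.rrr_aur`  | 0.676 | used on BPH→AUR |
| Efficacy of combination vs monotherapy, TURP| `efficacy.rrr_turp` | 0.706 | used on BPH→TURP |

## Costs (2018 US$)

| Published input                          | Field (`costs.`)              | Base   | Role |
|------------------------------------------|-------------------------------|--------|------|
| Combination drug, per annum              | `annual_drug_combination`     | 464.97 | used; BPH occupancy |
| Tamsulosin, per annum                    | `annual_drug_tamsulosin`      | 55.79  | used; BPH occupancy |
| Managing a patient in BPH state, per annum| `annual_bph_management`      | 471    | used; BPH occupancy |
| Managing an AUR episode                  | `aur_episode`                 | 1312   | used; per event |
| TURP procedure                           | `turp_procedure`              | 6334   | used; per procedure (first and repeat) |
| Medical intervention, per annum          | `annual_medical_intervention` | 371    | used; medical-state occupancy |
| (not published) recovery follow-up       | `recovery_followup`           | 0      | placeholder for the one-off first-recovery charge |

## Utilities

| Published input             | Field (`utilities.`) | Base  | Role |
|-----------------------------|----------------------|-------|------|
| BPH mild / moderate / severe| —                    | 0.993 / 0.903 / 0.79 | not modelled separately (single-state design) |
| BPH, severity-weighted      | `u_bph`              | 0.876 | used |
| AUR                         | `u_aur`              | 0.25  | used |
| TURP (and repeat TURP)      | `u_turp`             | 0.25  | used |
| Medical intervention        | `u_medical`          | 0.25  | used |
| Recovery                    | `u_recovery`         | 1.0   | used |
| Death                       | `u_death`            | 0     | fixed |

## PSA distribution notes

Where a distribution's published mean differs from the base-case value
above (BPH→TURP 0.0208 vs 0.021; recovery→medical 0.0743 vs 0.0467;
medical→second TURP 0.0614 vs 0.036; BPH→AUR 0.02 vs 0.004), the base
case governs deterministic runs and the distribution governs PSA
sampling, each exactly as published in its own role. Gamma rates are
rederived as shape/mean (`mean_override`) because the published rate
constants contradict the published means.
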