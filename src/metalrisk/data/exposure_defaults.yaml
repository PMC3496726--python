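# Default exposure parameters.
#
# Survey-derived parameters (body weight, activity hours, dietary intakes,
# water ingestion, exposure duration) carry the adult moments of the study
# population's questionnaire and default to lognormal distributions.
# Literature parameters (soil/air intake rates, skin area, adherence,
# absorption) are fixed point values; see docs/methods.md for provenance,
# including the back-calculated soil ingestion rate.
BW: {distribution: lognormal, mean: 62.58, sd: 10.23, units: kg, note: survey}
hours_indoor: {distribution: lognormal, mean: 8.47, sd: 3.99, units: h/day, note: survey}
hours_outdoor: {distribution: lognormal, mean: 5.84, sd: 3.98, units: h/day, note: survey}
hours_sleep: {distribution: lognormal, mean: 9.24, sd: 2.14, units: h/day, note: survey}
IR_water: {distribution: lognormal, mean: 1.88, sd: 0.62, units: L/day, note: survey}
ED: {distribution: lognormal, mean: 35.35, sd: 18.68, units: year, note: survey}
EF: {distribution: fixed, mean: 365.0, units: day/year, note: residents exposed daily}
IR_rice: {distribution: lognormal, mean: 360.29, sd: 71.92, units: g/day, note: survey}
IR_flour: {distribution: lognormal, mean: 6.29, sd: 17.38, units: g/day, note: survey}
IR_pakchoi: {distribution: lognormal, mean: 171.76, sd: 82.74, units: g/day, note: survey}
IR_cabbage: {distribution: lognormal, mean: 63.53, sd: 38.66, units: g/day, note: survey}
IR_spinach: {distribution: lognormal, mean: 30.44, sd: 19.36, units: g/day, note: survey}
IR_celery: {distribution: lognormal, mean: 24.26, sd: 11.49, units: g/day, note: survey}
IR_pork: {distribution: lognormal, mean: 56.85, sd: 25.01, units: g/day, note: survey}
IR_egg: {distribution: lognormal, mean: 45.44, sd: 25.97, units: g/day, note: survey}
IR_soil: {distribution: fixed, mean: 22.8, units: mg/day, note: back-calculated; within EPA adult central range 20-50}
IR_air: {distribution: fixed, mean: 14.5, units: m3/day, note: EPA adult inhalation rate}
SA_soil: {distribution: fixed, mean: 5700.0, units: cm2, note: EPA default exposed skin area}
AF_soil: {distribution: fixed, mean: 0.07, units: mg/cm2-day, note: EPA adult adherence factor}
SA_water: {distribution: fixed, mean: 18000.0, units: cm2, note: whole-body area for bathing contact}
AF_water: {distribution: fixed, mean: 0.01, units: mg/cm2-day, note: nominal water-film loading}
ABS_default: {distribution: fixed, mean: 0.001, units: "1", note: dermal absorption fraction, metals}
ABS_Cd: {distribution: fixed, mean: 0.01, units: "1", note: dermal absorption fraction, cadmium}
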