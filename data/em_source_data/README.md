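# Published immunogold count tables (not included)

The per-micrograph stereology tables deposited with eLife article 46421
("Figure 1—source data 1/2", "Figure 3—source data 1") are third-party
supplements and are not redistributed in this repository.

To run the published-target checks in `tests/test_acceptance.py`, download
them from the article and save them here as delimited text with one row per
micrograph and columns:

```
image_id, image_area_um2, n_dcv, gold_dcv, gold_cytoplasm,
gold_membrane, gold_outside, bouton_area_um2
```

as the files:

* `fig1_anp_counts.csv` — ANP-reporter immuno-EM counts
* `fig1_control_counts.csv` — non-expressing control counts
* `fig3_dtk_counts.csv` — dTK-reporter immuno-EM counts

`nprrquant.read_stereology_summary` reads these and
`density_report_from_counts` recomputes the DCV/bouton density ratios
(expected ≈ 14.26 and ≈ 22.19) and the control background (< 0.6 gold/µm²).
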