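# Supplementary-data transcription

The headline analysis (19-study ischaemic-stroke network, 15 comparators)
requires arm-level data and study covariates that are distributed only as a
supplementary DOCX of the source publication (Tables A and B of its
Supplementary File S1). There is no machine-readable accession, so this
repository does **not** ship those data; transcribe them manually into this
directory to enable the full reproduction:

- `arms.csv` — header `study,treatment,r,n`; one row per trial arm with
  ischaemic-stroke event count `r` out of `n` randomized patients.
  Zero-event arms are entered verbatim (e.g. the adjusted-dose-VKA arm of
  the MWNAF trial with `r = 0`).
- `covariates.csv` — header
  `study,prev_stroke_tia_pct,male_pct,mean_age_yr,follow_up_months`;
  percents on the 0–100 scale, age in years, follow-up in months; leave the
  cell empty when a study does not report the value.
- `coding.txt` — one treatment label per line, **placebo first**,
  adjusted-dose VKA second; labels must match the `treatment` column of
  `arms.csv`.

With these files present, `tests/test_acceptance.py` runs the
transcription-dependent reproduction tests (they fail with a clear message
otherwise), and `python scripts/acceptance.py --seed 1 --out results.json
--data-dir data/supplementary` recomputes every data-dependent target.
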