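"""Generate a synthetic TMA cohort and apply the over-fixation QC filter.

The default configuration mirrors the modeled study: 11 colorectal-cancer
patients (3 MMR-deficient), 623 routinely fixed cores plus 337 over-fixed
stock cores whose PMS2 staining is lost and which QC removes.
"""

from mmrtriage import CohortConfig, apply_qc_filter, generate_cohort

cohort = generate_cohort(CohortConfig(), seed=1)
print(f"patients: {len(cohort.patients)} "
      f"({(cohort.patients.mmr_status == 'deficient').sum()} deficient)")
print(cohort.patients[cohort.patients.mmr_status == "deficient"])

filtered = apply_qc_filter(cohort)
print(f"\ncores generated: {len(cohort.cores)}; "
      f"QC excluded {filtered.n_qc_excluded} over-fixed cores; "
      f"{len(filtered.cores)} retained")

unstained = filtered.sections[~filtered.sections.stained]
print(f"ground-truth unstained sections among retained cores: {len(unstained)}")
# Each deficient patient's tumor cores are unstained exactly for the
# proteins in that patient's loss pattern (e.g. the MLH1+PMS2 pair).
print(unstained.protein.value_counts().to_string())
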