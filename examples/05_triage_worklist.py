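"""Build the triage worklist: flagged cores first, most suspicious on top.

Flagging never drops a core — it only re-prioritizes the pathologist's
review order; a patient is prioritized when any of their cores is
flagged.
"""

from mmrtriage import PipelineConfig, build_worklist, run_pipeline

result = run_pipeline(PipelineConfig(), seed=1)
worklist = build_worklist(result.core_scores, cutoff=result.cutoff_sis)

print(f"flagged {worklist.n_flagged} of {worklist.n_total} cores "
      f"at cutoff {worklist.cutoff:.2f}")
print(f"prioritized patients: {worklist.prioritized_patients()}")
print("\ntop of the worklist (lowest minimum SIS = most suspicious):")
print(worklist.entries.head(8).to_string(index=False))
print("\nfirst unflagged entry:")
print(worklist.entries[~worklist.entries.flag].head(1).to_string(index=False))
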