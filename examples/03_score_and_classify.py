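"""Score core sections with SIS = B*W and call cores at a cutoff.

A core is represented by the minimum SIS over its four MMR protein
sections, because one unstained protein is the pathological finding.
"""

from mmrtriage import classify_core, core_representative, pathologist_core_call, section_sis

# Four protein sections of one core: MSH2/MSH6 well stained, the
# MLH1/PMS2 pair lost (background-level W only).
sections = {
    "MLH1": section_sis(B=12.0, W=0.02),   # 0.24 — essentially unstained
    "PMS2": section_sis(B=8.0, W=0.01),    # 0.08
    "MSH2": section_sis(B=85.0, W=0.70),   # 59.5
    "MSH6": section_sis(B=78.0, W=0.64),   # 49.9
}
rep = core_representative(sections)
print(f"per-protein SIS: { {k: round(v, 2) for k, v in sections.items()} }")
print(f"core representative (minimum): {rep:.2f}")
print(f"call at cutoff 55: {classify_core(rep, cutoff=55.0)}")
# The minimum exposes the lost protein even though two sections score high.

calls = {"MLH1": False, "PMS2": False, "MSH2": True, "MSH6": True}
print(f"pathologist-style call (any unstained protein): {pathologist_core_call(calls)}")
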