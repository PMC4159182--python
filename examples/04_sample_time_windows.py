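"""Biomarker sample selection against DAS treatment-episode time windows.

Serum samples are matched to each treatment episode's DAS start and end
dates: at most 30 days before / 40 days after the start, 75 before / 152
after the end (inclusive). The summary mirrors the per-treatment biobank
report: patients, globally eligible sera, and per-window sample/patient
counts.
"""

from cohortfusion import (SynthConfig, WindowConfig, eligible_samples,
                          generate, summarize_selection)

store = generate(SynthConfig(ra_n=400, psoriasis_n=10, seed=3))

cfg = WindowConfig(start_before=30, start_after=40,
                   end_before=75, end_after=152,
                   allowed_statuses=frozenset({"available"}))

print("eligible serum samples:", len(eligible_samples(store, cfg)),
      "of", len(store.samples), "total specimens")

sel = summarize_selection(store, ["A", "B", "C"], cfg)
print(sel.summary.to_string(index=False))
# start_window_samples counts sera drawn around treatment start (baseline
# biomarkers); end_window_samples around the last on-treatment DAS28
# (response biomarkers). A sample can serve both windows.
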