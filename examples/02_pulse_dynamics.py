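"""Pulsatile apical-area dynamics: align live traces to anaphase,
test pre-anaphase constriction and compare sine-fit pulse amplitudes.

Mitotic traces carry a constriction event reaching its minimum at the
annotated anaphase frame; both groups oscillate, the mitotic group with
twice the interphase sine amplitude.
"""

from apicodyn.pulses import (aggregate_aligned, align_traces,
                             compare_amplitudes, fit_all, pre_anaphase_test)
from apicodyn.synthetic import TraceParams, generate_traces

params = TraceParams()  # 29 mitotic + 54 non-mitotic cells, 5-min frames
traces, truth = generate_traces(params, seed=3)

aligned = align_traces(traces)
agg = aggregate_aligned(aligned)
mit = agg[agg["group"] == "mitotic"].set_index("rel_t_min")["mean"]
print(f"mitotic mean curve: minimum {mit.min():.3f} x own mean "
      f"at T{mit.idxmin():+.0f} min (T0 = anaphase)")

pre = pre_anaphase_test(aligned, lag=30.0)
print(f"paired t-test, T-30 vs T0: t = {pre.statistic:.2f}, p = {pre.p:.2g}")

fits = fit_all(traces)
res = compare_amplitudes(fits)
m, n = (g.mean for g in res.groups)
print(f"sine amplitudes: mitotic {m:.3f} vs non-mitotic {n:.3f} "
      f"(fraction of own mean area); t-test p = {res.p:.2g}")
print("-> mitotic constriction is the highest-amplitude apical pulse.")
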