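"""The cohort statistics ladder on a simulated three-group study.

Healthy controls vs two insomnia treatment arms; N2 sleep duration and
the arousal index are generated from the true ALPS index, so the
screen and backward elimination have a known signal to find.
"""

import glymphalps as ga
from glymphalps.cohort import CohortSpec

table, _ = ga.simulate_cohort(CohortSpec(seed=11), imaging=False)
print(f"cohort: {table.subject_id.nunique()} subjects, {len(table)} visits\n")

# three-group comparison of the index at baseline
cmp = ga.compare_groups(table, "alps")
print(f"ALPS by group: F = {cmp.statistic:.2f}, p = {cmp.p:.2g}")
for g, (m, s, n) in cmp.group_stats.items():
    print(f"  {g:10s} {m:.3f} +/- {s:.3f}  (n={n})")

# univariate screen (patients only, baseline) then backward elimination
candidates = ["age", "education", "total_sleep_time", "n2_duration", "arousal_index", "waso", "ahi"]
uni = ga.univariate_screen(table, candidates=candidates)
screened = [u.variable for u in uni if u.flagged]
print(f"\nscreened at p<0.2: {screened}")

model = ga.backward_select(table, screened=screened, adjust=ga.ADJUST_MODEL_I, p_removal=0.1, model_tag="model_I")
print("model I (adjusted for gender, age), retained after elimination:")
for term, (beta, lo, hi, p) in model.params.items():
    tag = "forced" if term in model.adjusted_for else "kept"
    print(f"  {term:15s} beta {beta:+.4f} (95% CI {lo:+.4f} to {hi:+.4f}), p = {p:.3g} [{tag}]")

# pre/post treatment contrast
for group in ("true_rTMS", "sham_rTMS"):
    r = ga.paired_prepost(table, "alps", group)
    print(f"\n{group}: ALPS change {r.mean_diff:+.3f} (95% CI {r.ci_low:+.3f} to {r.ci_high:+.3f}), "
          f"t = {r.t:.2f}, p = {r.p:.2g}, n = {r.n_pairs} pairs")
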