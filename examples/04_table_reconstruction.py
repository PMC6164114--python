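"""Recover integer confusion matrices from rounded published percentages.

Given a diagnostic-accuracy table printed to one decimal and the cohort
sizes, an exhaustive integer search finds every (tp, fn, fp, tn) whose
metrics round to the printed values -- and proves it when no matrix can.
"""

from breathdx import compute_metrics, reconstruct_confusion

# external validation row: 12 cases, 29 controls, sens 75.0%, spec 96.6%
res = reconstruct_confusion(
    {"sensitivity": 75.0, "specificity": 96.6}, n_cases=12, n_controls=29
)
cm = res.solutions[0]
print(f"unique solution: tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}")
print("implied metrics:", compute_metrics(cm).rounded())

# adding the row's printed accuracy of 85.4% makes the system unsolvable:
bad = reconstruct_confusion(
    {"sensitivity": 75.0, "specificity": 96.6, "accuracy": 85.4},
    n_cases=12, n_controls=29,
)
print(f"\nwith accuracy 85.4%: consistent={bad.consistent}")
print("maximal consistent subsets:", bad.maximal_subsets)
# The counts above give accuracy 37/41 = 90.2%, so the printed 85.4% is an
# internal contradiction of the published row, not a reachable value.
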