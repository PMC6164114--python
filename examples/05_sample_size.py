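"""Sample size for a target standard error of classification accuracy.

From SE = sqrt(C(100 - C)/n): solving for n at an expected accuracy of
C = 80% and a tolerated standard error of 3 percentage points.
"""

from breathdx import sample_size

for C, SE in [(80, 3), (90, 3), (50, 5)]:
    n = sample_size(C, SE)
    print(f"C = {C}%  SE <= {SE}%  ->  n >= {n}")
# At 80% expected accuracy, keeping the standard error under 3 points
# requires at least 178 subjects in the training set.
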