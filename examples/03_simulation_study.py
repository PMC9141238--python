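"""Small-scale size and power study with the built-in simulator.

Simulates case-control data under the X-linked disease model
logit Pr(D=1) = a1 + a2*sex + a3*x3 + beta*G, first with beta = 0 to check
type-I error, then with beta = 0.15 across X-inactivation patterns to
compare power. Sizes are kept small so the script runs in about a minute;
scripts/full_scale_size.py runs the full-scale version.
"""

from xcmax4 import SimulationConfig, estimate_power, estimate_size
from xcmax4.data import XCI_E

# --- type-I error at nominal 5% and 1%, 2000 null replicates -------------
null_cfg = SimulationConfig(beta=0.0, n_cases=300, n_controls=300)
size = estimate_size(null_cfg, tests=("xcmax4", "fm02"), n_reps=2000,
                     alpha_levels=[0.05, 0.01], seed=1)
print("empirical size (beta = 0):")
print(size.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# --- power across XCI patterns at beta = 0.15 ----------------------------
cfgs = [SimulationConfig(beta=0.15, xci=g, n_cases=1000, n_controls=1000)
        for g in (0.0, 1.0, 2.0)]
cfgs.append(SimulationConfig(beta=0.15, xci=XCI_E, n_cases=1000, n_controls=1000))
power = estimate_power(cfgs, tests=("xcmax4", "fm01", "fm02"), n_reps=200,
                       alpha=0.01, seed=2)
print("\nempirical power (beta = 0.15, alpha = 0.01):")
print(power.pivot(index="xci", columns="test", values="power"))

print("""
Under the null the rejection rates sit at (or, for XCMAX4 at the 1% level,
slightly below) the nominal level: the rhombus bound is an upper bound on
the p-value, so the test is never anti-conservative. In the power table
FM02 leads under random inactivation (XCI-R, its own modelling assumption),
FM01 leads under escape (XCI-E), and XCMAX4 tracks the best fixed-coding
test within a few points everywhere without knowing the true pattern.""")
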