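"""Derive population-specific upper limits of normal from baseline panels.

Each analyte's limit is the trimmed mean of the cohort's week-0 values
(extreme 5% discarded, 2.5% per tail); ALT is sex-stratified.  Compare
with the packaged published limits for the emulated cohort.
"""

from dilipipe import derive_uln, generate_cohort, published_uln
from dilipipe.simulate import SimConfig

cohort, _ = generate_cohort(SimConfig(seed=1))
derived = derive_uln(cohort, trim_fraction=0.05)
published = published_uln()

print(f"{'analyte':<12}{'derived':>10}{'published':>12}")
for name in ("alt_female", "alt_male", "ast", "alp", "tbil", "dbil"):
    print(f"{name:<12}{getattr(derived, name):>10.1f}{getattr(published, name):>12.1f}")
# Derived limits are trimmed means of the baseline distribution, so they sit
# near the baseline medians; the published limits were derived the same way
# on the real cohort and serve as the default reference set.
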