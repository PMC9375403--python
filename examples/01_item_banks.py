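"""Build the two archetype item banks and inspect their structure.

Archetype 1 mimics classical-test-theory instruments (near-identical item
locations, widely spread category thresholds); archetype 2 mimics Rasch-built
instruments (an item hierarchy along the trait, tight thresholds).
"""

import numpy as np

from pcmcal import expected_score, make_archetype_bank

for archetype in (1, 2):
    bank = make_archetype_bank(J=4, M=3, archetype=archetype)
    print(f"archetype {archetype}: locations {np.round(bank.locations, 3)}")
    print("thresholds:")
    print(np.round(bank.thresholds, 3))

# the expected total score is the instrument's "scoring curve" over the trait
bank = make_archetype_bank(J=4, M=3, archetype=2)
for theta in (-2.0, 0.0, 2.0):
    print(f"expected total score at theta={theta:+.0f}: {expected_score(theta, bank):.2f} / 8")
# reading: a trait 2 logits above the item centre already scores ~7 of 8
# points, i.e. the instrument is poorly targeted for such a population.
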