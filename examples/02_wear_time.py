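"""Troiano non-wear detection on a counts-per-minute vector.

Constructs a CPM sequence with an off-body block — 70 minutes of zeros with
a brief 2-minute low-count interruption — flanked by active minutes, and
shows which minutes the Troiano rule (>= 60 min of zeros, interruptions of
at most 2 consecutive minutes below 100 CPM) flags as non-wear.
"""

import numpy as np

from actikit import troiano_wear_mask

cpm = np.concatenate([
    np.full(10, 2500),   # 10 active minutes (walking)
    np.zeros(30),        # device comes off
    [60, 40],            # a 2-minute sub-100 interruption (allowed)
    np.zeros(38),        # still off
    np.full(10, 2500),   # back on, walking again
]).astype(int)

mask = troiano_wear_mask(cpm)
print("minutes:", len(cpm), " wear:", mask.wear_minutes, " non-wear:", mask.nonwear_minutes)
print("flags:", "".join(str(f) for f in mask.flags))

# The 70-minute zero block qualifies despite the interruption, so all 70 of
# its minutes (interruption included) are flagged 0; the walking minutes at
# both ends stay wear time. A 3-minute interruption, or any minute >= 100
# CPM, would have split the block below the 60-minute threshold.
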