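"""Erosion, dilation, opening and closing on a small binary image.

Builds a 12x12 binary image with a black block, a one-pixel black speck,
and a small white hole, then shows what each flat operator does to the
black pixel count.
"""

import numpy as np

from topomorph import closing, dilate, erode, opening, square_se_sequence

img = np.ones((12, 12), dtype=np.uint8)
img[2:9, 2:9] = 0  # black block
img[4:6, 4:6] = 1  # 2x2 white hole inside it
img[10, 10] = 0  # isolated black speck

seq = square_se_sequence(2)
b1, b2 = seq[1], seq[2]

print("black pixels in the input:           ", (img == 0).sum())
print("after erosion  (black grows):        ", (erode(img, b1) == 0).sum())
print("after dilation (black shrinks):      ", (dilate(img, b1) == 0).sum())
print("after opening  (white hole filled):  ", (opening(img, b2) == 0).sum())
print("after closing  (black speck removed):", (closing(img, b2) == 0).sum())
# The 2x2 hole disappears under opening with the 3x3 square, and the
# isolated speck disappears under closing with the same element, while the
# large block survives both: small-scale features are removed selectively.
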