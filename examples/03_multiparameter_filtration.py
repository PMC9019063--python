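"""Multi-parameter levels, alternating sequences, and nondecreasing paths.

Alternating opening/closing compositions index a multifiltration: the
black set X_u of the composite M_u grows monotonically with the
multi-index u.  A nondecreasing path through the index grid therefore
yields an ordinary one-parameter filtration, whose persistence can be
computed as usual.
"""

import numpy as np

from topomorph import (
    MultiFiltrationSpec,
    alternating_apply,
    nondecreasing_path,
    persistence,
    square_se_sequence,
)
from topomorph.synth import default_phantom_spec, make_phantom, salt_pepper

clean, _ = make_phantom(default_phantom_spec())
noisy = salt_pepper(clean, 0.2, seed=0)

spec = MultiFiltrationSpec.opening_closing(square_se_sequence(3))

u, v = (-1, 1), (-1, 2)  # componentwise u <= v, both alternating
xu = alternating_apply(noisy, u, spec) == 0
xv = alternating_apply(noisy, v, spec) == 0
print(f"|X_{u}| = {xu.sum()}  |X_{v}| = {xv.sum()}  contained: {(xu <= xv).all()}")
# Containment X_u <= X_v holds for every comparable pair of alternating
# multi-indices: the levels form a genuine 2-parameter filtration.

path = [(-2, 0), (-2, 1), (-1, 1), (0, 1), (0, 2), (0, 3)]
filt = nondecreasing_path(noisy, path, spec)
diagram = persistence(filt)
print("pairs along the path:", sorted(diagram.pairs)[:8], "...")
print("levels on the path:", len(filt), " (a valid one-parameter filtration)")
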