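"""Matching-rate bookkeeping for a registration run.

The screening metrics mirror the standard benchmark table for this family of
methods: initial matches, matches surviving all screening, wrong pairs among
the survivors (judged against a known transform at 3 px), and the matching
rate 100*(screened - mismatches)/screened.
"""

import math

from georeg import evaluate_result, register, synth_texture_pair
from georeg.types import SimilarityTransform

truth = SimilarityTransform.about_center((256, 256), alpha=math.radians(30), du=12, dv=-7)
pair = synth_texture_pair(seed=0, size=256, transform=truth, noise_sigma=2.0)
result = register(pair.image_a, pair.image_b)

m = evaluate_result(result, truth, tol_px=3.0)
print(f"initial matching points      : {m.n_initial}")
print(f"matching points after screen : {m.n_screened}")
print(f"mismatches after screening   : {m.n_mismatch}")
print(f"matching rate                : {m.rate:.2f}%")
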