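"""Apply the four sampling-design perturbations to one panel.

Each design mimics a realistic monitoring bias; because site removal depends
on abundance, the induced missingness is MNAR (missing not at random).
"""

import numpy as np

import flywaybench as fb

sites = fb.generate_sites(100, seed=4)
panel, _ = fb.generate_counts(sites, beta0=np.log(20.0), site_sd=1.2,
                              family_id="nb2", dispersion=0.6, seed=5)
panel = fb.apply_missingness(panel, 0.12, seed=6)
panel = fb.filter_min_surveys(panel, min_surveys=15)

for design_id in ("raw", "larger_out", "smaller_out", "unbalanced"):
    out = fb.apply_design(panel, fb.DesignSpec(design_id, seed=7))
    obs = out.counts[out.observed_mask]
    print(f"{design_id:12s} sites {out.n_sites:3d}  observed cells {obs.size:5d}  "
          f"total count {obs.sum():9.0f}")
# larger_out removes ~40-60% of the count mass with only 10% of sites (the
# biggest sites dominate); smaller_out barely moves the total; unbalanced
# keeps all sites but masks early large-site and late small-site cells.
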