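"""Chromatin condensation parameter on synthetic nuclei.

Renders nucleus phantoms with increasing numbers of bright heterochromatin
foci and computes the CCP: Sobel edge pixels divided by nuclear area.  More
foci mean more intensity edges inside the nucleus, so CCP rises; dividing
by area makes nuclei of different sizes comparable.
"""

from fibroquant import NucleusPhantomParams, ccp, render_nucleus

print(f"{'foci':>6} {'CCP':>8} {'edge px':>9} {'area px':>9}")
for n_foci in [0, 5, 10, 15, 25, 40, 60]:
    params = NucleusPhantomParams(n_foci=n_foci, noise_sd=0.0)
    image, mask = render_nucleus(params, seed=11)
    value = ccp(image, mask)
    print(f"{n_foci:>6} {value.value:>8.4f} {value.edge_pixels:>9} "
          f"{value.area_pixels:>9}")

print(
    "\nA focus-free noiseless nucleus has no internal edges (CCP = 0)."
    "\nCCP grows monotonically with the number of heterochromatin foci;"
    "\nthe edge threshold is relative (15% of the in-nucleus maximum"
    "\ngradient), so rescaling intensities does not change the value."
)
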