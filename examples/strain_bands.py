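"""From clinical IOP to the cyclic tensile strain applied in culture.

Treating the bovine eye globe as a pressurised thin-walled sphere
(r = 16.2 mm, t = 1.6 mm), the hoop stress sigma = p*r/2t set up by an
intraocular pressure maps to a tensile strain band across the 1-7 MPa
scleral stiffness range: the stiff end of the range bounds strain from
below, the compliant end from above.
"""

from fibroquant import strain_report

for label, iop_mmhg, sig in [("physiological (healthy IOP)", 27.0, 2),
                             ("pathological (glaucomatous IOP)", 60.0, 1)]:
    rep = strain_report(iop_mmhg, 16.2e-3, 1.6e-3, 1e6, 7e6, sig=sig)
    print(f"{label}: IOP {iop_mmhg:.0f} mmHg = {rep['iop_kpa']} kPa")
    print(f"  hoop stress  : {rep['stress_pa']:.0f} Pa")
    print(f"  strain band  : {rep['strain_min_pct']}% - {rep['strain_max_pct']}%")

print(
    "\nThe strain band is what a stretch device must deliver to mimic the"
    "\ncorresponding pressure state for cells cultured on a membrane."
)
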