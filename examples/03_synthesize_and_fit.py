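"""Round-trip a known network through a synthetic confocal volume.

A two-filament scene (radius 0.25 um, lengths 4 um) is rendered as a noisy
two-channel z-stack at 120 nm voxels, then handed to the automated cylinder
fitter.  The fitted radii come out larger than 0.25 um: the point spread
function inflates apparent thickness, exactly as in real imaging where 25 nm
microtubules appear ~500 nm wide.
"""

import numpy as np

from mtmesh import fit_network, make_fixture_network, place_linkers, render_network

truth = make_fixture_network("motility_element")
vol_filament, vol_linker = render_network(truth, snr=10.0, seed=0)
print(f"rendered volume: {vol_filament.data.shape} voxels at "
      f"{vol_filament.spacing} um")

fitted, report = fit_network(vol_filament)
fitted = place_linkers(fitted, vol_linker)

print(f"true filaments  : {len(truth.filaments)}, fitted: {len(fitted.filaments)}")
print(f"foreground coverage: {report.coverage:.2f}")
for f in fitted.filaments:
    print(f"  {f.id}: length {f.length:.2f} um (true 4.00), "
          f"apparent radius {f.radius:.2f} um (true 0.25, PSF-inflated)")
print(f"kinesin linkers recovered from the second channel: {len(fitted.linkers)}")
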