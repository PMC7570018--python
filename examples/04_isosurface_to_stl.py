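"""Extract an isosurface mesh from a rendered volume and write it as STL.

The STL file is the hand-off surface to external 3D tools; the extraction
level is a free parameter chosen by inspection, so we take the half-max.
"""

import tempfile
from pathlib import Path

from mtmesh import extract_isosurface, make_fixture_network, read_stl, render_network, write_stl

model = make_fixture_network("two_parallel")
volume, _ = render_network(model, snr=20.0, seed=1)

level = float(volume.data.max()) / 2
mesh = extract_isosurface(volume, level)
print(f"isosurface at level {level:.0f}: {len(mesh.vertices)} vertices, "
      f"{len(mesh.triangles)} triangles, area {mesh.area:.2f} um^2")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "network.stl"
    write_stl(mesh, path)
    back = read_stl(path)
    print(f"STL round trip: {path.stat().st_size} bytes, "
          f"{len(back.triangles)} triangles preserved")
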