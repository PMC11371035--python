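"""Headless batch processing over a JSON settings file.

Generates a 10-frame time series with a drifting lattice spacing, writes a
settings file, runs the equator pipeline over the whole directory (as the
`fiberfold equator` CLI command would) and prints the recovered trend.
"""

import json
import tempfile
from pathlib import Path

from fiberfold import run_headless
from fiberfold.synthgen import SyntheticSpec, generate_sequence

with tempfile.TemporaryDirectory() as td:
    td = Path(td)
    spec = SyntheticSpec(shape=(128, 384), S10=50.0, noise="poisson", seed=3)
    generate_sequence(spec, 10, td / "frames", drift={"S10": 0.5})

    settings_path = td / "settings.json"
    settings_path.write_text(json.dumps({
        "calibration": {"wavelength_nm": 0.1033, "distance_mm": 3000.0,
                        "pixel_size_mm": 0.172},
        "equator": {"hk_list": [[1, 0], [1, 1], [2, 0]], "model": "gaussian"},
        "workers": 2,
    }, indent=2))

    df = run_headless(settings_path, td / "frames", "equator", td / "results")
    print(df[["filename", "S10_px", "d10_nm", "I11_over_I10", "flagged"]]
          .to_string(index=False))
    print("\nS10 drifts +0.5 px per frame by construction; d10 shrinks as the")
    print("filament lattice compresses. Equivalent CLI:")
    print("  fiberfold equator --settings settings.json --input frames/ --workers 2")
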