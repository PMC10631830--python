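"""Regenerate the packaged default normalized elastance curve.

Samples the double-Hill shape on 501 uniform cycle fractions, renormalizes
the peak to 1, and writes ``src/pvloop/data/default_elastance.csv``. Run from
the repository root after changing the shape parameters in
``pvloop.elastance``.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pvloop.elastance import double_hill  # noqa: E402

x = np.linspace(0.0, 1.0, 501)
e = double_hill(x)
e = e / e.max()
out = Path(__file__).resolve().parents[1] / "src" / "pvloop" / "data" / "default_elastance.csv"
pd.DataFrame({"t_norm": x, "e_norm": e}).to_csv(out, index=False, float_format="%.10g")
print(f"wrote {out} ({len(x)} samples, peak at x={x[np.argmax(e)]:.3f})")
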