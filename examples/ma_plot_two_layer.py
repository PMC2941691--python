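"""Render a T/C View MA plot with its machine-readable overlay.

Runs a synthetic experiment through the ratio statistics, renders the
480x480 static layer for one T/C and prints a few overlay records — the
second display layer an interactive front end would consume.
"""

import json
import tempfile
from pathlib import Path

from microtc.plots import PlotStyle, ma_points_for_tc, render_ma_plot
from microtc.synth import Spike, generate_experiment, ice1_like_spec
from microtc.tc import compute_tc_stats, enumerate_tcs

spec = ice1_like_spec(seed=7, n_features=300,
                      spikes=(Spike("g00005", {"cold": "24 hr"}, 3.0),
                              Spike("g00006", {"cold": "24 hr"}, -2.0)))
exp = generate_experiment(spec)
tc = next(t for t in enumerate_tcs(exp.design.sample_sets, exp.design.factors)
          if t.tc_id == "wild_type_24_hr__vs__wild_type_none")
points = ma_points_for_tc(tc.tc_id, compute_tc_stats(exp.matrix, tc))

outdir = Path(tempfile.mkdtemp())
img, overlay = render_ma_plot(points, PlotStyle(title=tc.name),
                              str(outdir / "ma.png"), str(outdir / "ma.overlay.jsonl"))
print(f"raster:  {img}")
records = [json.loads(l) for l in open(overlay)]
print(f"overlay: {len(records)} point records, e.g.")
for rec in records[:3]:
    print(f"  {rec}")
spiked = [r for r in records if r["item_id"] in ("g00005", "g00006")]
for rec in spiked:
    print(f"  spiked {rec['item_id']}: M={rec['m']:+.2f} at pixel ({rec['px']:.0f},{rec['py']:.0f}), {rec['color']}")
# Points are colored by P value (blue <0.01, green 0.01-0.05, yellow >0.05);
# pixel coordinates let a front end highlight points without re-plotting.
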