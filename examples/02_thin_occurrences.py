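"""Clean, deduplicate and spatially thin an occurrence CSV.

Writes a tiny CSV (including a bad row and a duplicate), then runs the
standard cleaning chain and prints the provenance accounting.
"""

import tempfile
from pathlib import Path

from zonarisk import deduplicate, load_occurrences, thin_spatial
from zonarisk.occurrences import pairwise_min_distance_km

csv = """id,lon,lat,status,source
r1,32.55,15.60,invaded,survey
r2,32.55,15.60,invaded,survey
r3,32.56,15.61,invaded,survey
r4,33.10,15.95,native,literature
r5,181.0,15.0,native,typo
r6,30.20,13.40,invaded,survey
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "occ.csv"
    path.write_text(csv)
    occ = load_occurrences(path)       # r5 dropped: longitude out of range
    occ = deduplicate(occ)             # r2 dropped: exact coordinate repeat
    occ = thin_spatial(occ, min_km=10) # r3 dropped: ~1.3 km from r1

for step in occ.provenance:
    print(f"{step.step:>22}: {step.n_in} in -> {step.n_kept} kept ({step.n_removed} removed)")
print(f"retained ids: {occ.records['id'].tolist()}")
print(f"minimum pairwise distance: {pairwise_min_distance_km(occ):.1f} km (>= 10 required)")
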