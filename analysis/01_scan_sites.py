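"""Scan toy closed/open tetramer structures for divalent-cation sites.

Builds two C4-symmetric toy tetramers whose per-chain aspartate pair sits
at 1.05 nm (closed-like geometry) or 1.25 nm (open-like geometry, the
helix-rotation mimic), scans both with the acidic-pair Calpha criterion,
and tabulates the per-chain distances and site presence.

Writes results/sites_closed.tsv and results/state_comparison.csv.
"""
from pathlib import Path

import pandas as pd

import mgbind as mg
from mgbind import presets
from mgbind.pipeline import compare_states

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

closed = presets.toy_closed_structure()
opened = presets.toy_open_structure()

sites = mg.scan_sites(closed)
rows = [{"site_id": s.site_id, "chain": p.residue_a[0],
         "res_a": p.residue_a[1], "res_b": p.residue_b[1],
         "pair_class": p.pair_class, "ca_distance_nm": round(p.ca_distance, 4),
         "cutoff_nm": p.threshold}
        for s in sites for p in s.member_pairs]
pd.DataFrame(rows).to_csv(OUT / "sites_closed.tsv", sep="\t", index=False)

comparison = compare_states(closed, opened, [(100, 105)])
comparison.to_csv(OUT / "state_comparison.csv", index=False)

print(f"closed-state geometry: {len(sites)} DD sites (one per chain), "
      f"Calpha distance {sites[0].member_pairs[0].ca_distance:.2f} nm "
      f"< 1.1 nm cutoff")
print(f"open-state geometry:  {len(mg.scan_sites(opened))} sites -- the "
      f"0.20 nm pair expansion abolishes every site")
print(f"wrote {OUT/'sites_closed.tsv'} and {OUT/'state_comparison.csv'}")
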