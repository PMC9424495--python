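"""Hypergeometric overrepresentation analysis of a query gene list.

Gene sets (GMT format) are tested for overlap enrichment against an
expressed-gene universe; sets with < 3 or > 1000 within-universe members
are excluded and p-values are BH-corrected across all sets pooled
(significant at FDR < 0.1).
"""

import tempfile
from pathlib import Path

import thkinetics as tk

universe = [f"gene{i:03d}" for i in range(200)]
query = universe[:20]  # e.g. the Independent genes of the hybrid lineage

gmt = "\n".join([
    "stat_targets\tSTAT1/4 target genes\t" + "\t".join(universe[:15]),
    "gata3_targets\tGATA-3 target genes\t" + "\t".join(universe[100:140]),
    "housekeeping\tunrelated set\t" + "\t".join(universe[150:170]),
]) + "\n"

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "sets.gmt"
    path.write_text(gmt)
    collection = tk.read_gmt(path, source_label="demo")

result = tk.run_ora(query, universe, collection, min_size=3, max_size=1000,
                    fdr=0.1)
cols = ["set_name", "overlap", "set_size", "p_value", "q_value", "significant"]
print(result[cols].to_string(index=False))
# 'stat_targets' overlaps the query in 15/15 members and dominates;
# overlap k, set size m, query size n and universe size N parameterise
# the hypergeometric upper tail P(X >= k).
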