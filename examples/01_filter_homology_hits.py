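"""Filter homology hits by identity and stitched query coverage.

Builds a tiny tabular homology table in memory: three subjects against a
5,294 bp TE query — one full-length high-identity hit, one hit split into
two HSPs that jointly cover enough of the query, and one truncated copy.
Only subjects whose HSPs all exceed 80% identity and whose stitched
coverage strictly exceeds 70% of the query (3,705 bp) are retained.
"""

from httdetect import blast_filter as bf

QUERY_LEN = 5294

rows = [
    # full-length, 95% identity -> retained
    "TEq\tscafA\t95.0\t5294\t265\t0\t1\t5294\t101\t5394\t0.0\t9000",
    # two HSPs jointly covering 1..2000 + 2300..4800 = 4501 bp -> retained
    "TEq\tscafB\t91.0\t2000\t180\t0\t1\t2000\t501\t2500\t0.0\t3200",
    "TEq\tscafB\t89.5\t2501\t262\t0\t2300\t4800\t2801\t5301\t0.0\t4000",
    # half-length copy -> dropped (2647 bp < 3705 bp threshold)
    "TEq\tscafC\t97.0\t2647\t79\t0\t1\t2647\t9001\t11647\t0.0\t4500",
]

with open("/tmp/example_hits.tsv", "w") as fh:
    fh.write("\n".join(rows) + "\n")

hsps = bf.parse_blast_tab("/tmp/example_hits.tsv")
sets = bf.group_by_subject(hsps, QUERY_LEN,
                           species={"scafA": "Cotesia vestalis",
                                    "scafB": "Plutella xylostella",
                                    "scafC": "Drosophila ficusphila"})

print(f"coverage threshold: >{bf.coverage_threshold_bp(QUERY_LEN, 0.70)} bp "
      f"of the {QUERY_LEN} bp query")
for hs in sets:
    bp, frac = bf.query_coverage(hs)
    print(f"  {hs.subject_id}: {len(hs.hsps)} HSP(s), union {bp} bp "
          f"({frac:.1%} of query)")

kept = bf.select_hits(sets, min_identity_pct=80.0, min_cover_fraction=0.70)
print("retained:", [hs.subject_id for hs in kept])

copies = bf.copies_from_hits(kept)
for c in copies:
    print("renamed record:", bf.rename_record(c))
# The two retained records keep only accession, match range and species --
# the identifier format used for every downstream tree leaf.
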