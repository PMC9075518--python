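"""Column conservation of aligned ACD cores (sequence-logo data).

Aligns the five subcluster template cores in the anchored model column
space and prints per-column information content, highlighting that the
β7→β9 zone (the L-P / V-D doublets, the L89 glycine, the β9 motif) carries
the strongest conservation signal.
"""

from shsp import align_cores, build_default_model, column_stats, make_template

model = build_default_model()
cores = [(lab, make_template(lab).core_seqs[0]) for lab in
         ("A1", "A2", "B1", "B2", "B3")]
msa = align_cores(cores, model)
stats = column_stats(msa.rows, t=0.5)

print(f"alignment: {len(msa.rows)} cores x {msa.n_columns} columns\n")
print("segment  consensus  mean_IC(bits)")
by_seg: dict[str, list] = {}
for cs, seg in zip(stats, msa.column_labels):
    by_seg.setdefault(seg, []).append(cs)
for seg in dict.fromkeys(msa.column_labels):
    cols = by_seg[seg]
    cons = "".join(c.consensus for c in cols)
    ics = [c.information for c in cols if c.information is not None]
    print(f"{seg:7s}  {cons:15s} {sum(ics)/len(ics):5.2f}")

print(
    "\nHigh information content marks invariant anchors (β9, the L78\n"
    "doublets); 'x' columns vary between subclusters (loop fillers)."
)
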