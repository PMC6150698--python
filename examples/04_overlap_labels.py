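"""Parse cell-type nomenclature and decide anatomical overlap.

Overlap is directional: it asks whether the presynaptic type's boutons meet
the postsynaptic type's spines, at glomerulus resolution in the
protocerebral bridge, layer resolution in the fan-shaped body, and
individual-nodulus resolution.
"""

from cxscreen.anatomy import annotation_for, overlap, parse_type_name

ann = parse_type_name("PBG2-9.s-FBl3.b-NO2D.b")  # the P-F3N2d columnar type
for arbor in ann.arbors:
    print(f"  {arbor.region.label():>8}  {'/'.join(sorted(arbor.polarity))}")

lab = overlap(annotation_for("E-PG"), annotation_for("P-EN1"))
print(f"E-PG -> P-EN1: overlapping = {lab.overlapping}, "
      f"shared = {lab.shared_regions}")
# E-PG sends boutons to bridge glomeruli 1-8, P-EN1 spines cover 2-9: the
# shared territory is glomeruli 2-8, so the pair is a screening candidate.

rev = overlap(annotation_for("P-F3N2d"), annotation_for("E-PG"))
print(f"P-F3N2d -> E-PG: overlapping = {rev.overlapping} "
      "(its boutons sit in FB layer 3 and the noduli, never near E-PG spines)")
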