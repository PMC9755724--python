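"""De-novo discovery of a lineage-specific big exon by flank anchoring.

Simulates a four-taxon family where a ~251 aa exon arises by exonization on
the branch leading to clade {A, B} only.  Using carrier A (with its exon
annotation) as reference, every other leaf is scanned: the conserved
flanking regions are aligned, their boundaries projected onto the target,
and the intervening target segment is measured and classified by length
band (none < 150 aa <= 4a < 335 aa <= 4a-L).
"""

from exonevo import infer_big_exon
from exonevo.simulate import make_preset, simulate_family

records, maps, truth = simulate_family(make_preset("exonization_recovery"))
print("true carriers of the insert:", sorted(truth.carriers["4a"]))

ref_id = sorted(truth.carriers["4a"])[0]
reference = next(r for r in records if r.record_id == ref_id)

print(f"\nscanning against annotated reference {ref_id!r}:")
for target in records:
    if target.record_id == ref_id:
        continue
    call = infer_big_exon(
        target, reference, maps[ref_id],
        left_anchor="Nterm", right_anchor="MTBD",
    )
    span = f"[{call.interval.start},{call.interval.end})" if call.interval else "-"
    print(
        f"  {target.record_id}: class={call.class_label:5s} length={call.length:3d} "
        f"span={span:11s} anchor_confidence={call.anchor_confidence:.2f}"
    )
print(
    "\nCarriers are called '4a' with the insert located exactly; "
    "non-carriers yield length ~0 and class 'none'."
)
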