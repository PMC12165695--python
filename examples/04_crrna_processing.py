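"""crRNA processing arithmetic for the spacer-before-repeat architecture.

In this crRNA architecture the spacer precedes the repeat. A 5' label sits
at the spacer's 5' end, so the length of the labeled product after
processing locates the cut site relative to the spacer-repeat junction:
a 30 nt spacer yielding a 6-7 nt product means the cut falls 24 or 23 nt
upstream of the repeat, leaving a mature guide of about 60 nt once the
36 nt repeat is included.
"""

from hepnscout.crispr import infer_cleavage_offset, mature_crrna_length

for fragment in (6, 7):
    call = infer_cleavage_offset(spacer_len=30, fragment_len=fragment, repeat_len=36)
    print(
        f"{fragment} nt labeled product -> cut {call.offset_upstream_of_repeat} nt "
        f"upstream of the repeat; mature spacer {call.mature_spacer_len} nt; "
        f"mature crRNA {call.mature_crrna_len} nt"
    )

print(f"\nsanity: repeat 36 + mature spacer 24 = {mature_crrna_length(36, 24)} nt guide")
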