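"""Extract specificity and RRID snippets from a small plain-text article.

The article below mimics a methods section registering an antibody by RRID and
a results section discussing its specificity.  Extraction yields (1) windows of
at most three sentences around each specificity cue, kept only when they
mention an antibody, and (2) single-RRID context windows.
"""

from abspec import (
    extract_rrid_snippets,
    extract_spec_snippets,
    filter_antibody_snippets,
    parse_document,
)

ARTICLE = """\
Tissue was fixed in paraformaldehyde and embedded in paraffin. Purified \
anti-beta-Amyloid antibody (6E10) (Cat. No. 803003; RRID:AB_2564652) was \
obtained from a commercial vendor. Sections were incubated overnight.

Samples were washed three times. Some non-specific bands were detected at \
~55 kDa in both WT and APP/PS1 mice with the 6E10 antibody. Band intensities \
were quantified with image software.

The assay was highly specific for glucose, with no interference observed.
"""

doc = parse_document(ARTICLE, format="plain", doc_id="demo")

spec = filter_antibody_snippets(extract_spec_snippets(doc))
print(f"{len(spec)} antibody specificity snippet(s):")
for sn in spec:
    print(f"  cue={sn.cue!r} window={len(sn.sentences)} sentences")
    print(f"  text: {sn.text}")

rrid = extract_rrid_snippets(doc)
print(f"\n{len(rrid)} RRID snippet(s):")
for sn in rrid:
    print(f"  rrid={sn.rrid} ({sn.n_sentences} sentences)")
    print(f"  text: {sn.text}")

# The glucose sentence matches the "specific" cue but mentions no antibody, so
# it is filtered out; only the 6E10 statement and the RRID registration remain.
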