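# Default 13-gene telomerase-activity signature: a 2-gene constituent
# component and an 11-gene marker component.
#
# Only the constituent genes and three marker genes (LIN9, HELLS, POLE2) are
# named in the publication's main text; the full marker list is published in
# its supplementary material, which is not redistributed here.  The MARKERxx
# entries below are explicit placeholders: replace them with the published
# identifiers (matching your expression matrix's gene namespace) before
# scoring real data.  The scoring engine itself is signature-agnostic.
name: default-telomerase-13
constituent:
  - TERT
  - TERC
markers:
  - LIN9
  - HELLS
  - POLE2
  - MARKER04
  - MARKER05
  - MARKER06
  - MARKER07
  - MARKER08
  - MARKER09
  - MARKER10
  - MARKER11
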