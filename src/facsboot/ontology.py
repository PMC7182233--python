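"""Fixed ontology of coded facial movements.

The coding scheme follows the Facial Action Coding System (FACS): numbered
Action Units (single muscle movements, e.g. AU4 = Brow Lowerer) and Action
Descriptors (head/eye position codes such as AU52 = Head Turn Right), plus
two self-directed behaviour channels (FaceTouch, NeckTouch) coded alongside
the face because of their link to negative affective states.

``DEFAULT_ONTOLOGY`` lists the 24 AU/AD codes that survive the producer-count
inclusion filter in a guilt-induction study of this design and therefore
carry all downstream analyses.  ``STUDY2_AU_ALIAS`` is a 15-code alias list
for the judgement-study stage; the membership of that shorter list is not
fully determined by the source material (the two counts are mutually
inconsistent), so the alias here is a best-effort reading — numbered facial
AUs plus the shame-linked head-down code and the two self-directed channels —
and analyses default to the full 24-code set.

``NOT_VISIBLE`` is a reserved pseudo-code used in event tables to mark frame
ranges in which the whole face could not be seen; such frames are removed
from every frequency computation rather than zero-filled.
"""

from __future__ import annotations

#: Reserved event code marking frames where the face is not fully visible.
NOT_VISIBLE = "NotVisible"

#: The 24 retained AU/AD codes, in canonical (table) order.
DEFAULT_ONTOLOGY: tuple[str, ...] = (
    "AU1", "AU2", "AU4", "AU5", "AU7", "AU10", "AU12", "AU14", "AU17",
    "AU18", "AU20", "AU24", "AU51", "AU52", "AU54", "AU55", "AU56",
    "AU57", "AU59", "AU61", "AU62", "AU64", "FaceTouch", "NeckTouch",
)

#: Best-effort 15-code alias for the judgement-study stage (see module
#: docstring; flagged as inconsistent in docs/methods.md).
STUDY2_AU_ALIAS: tuple[str, ...] = (
    "AU1", "AU2", "AU4", "AU5", "AU7", "AU10", "AU12", "AU14", "AU17",
    "AU18", "AU20", "AU24", "AU54", "FaceTouch", "NeckTouch",
)

#: AU/AD codes kept regardless of producer counts: shame-associated head/eye
#: down codes and the self-directed behaviours.
FORCED_INCLUDE: tuple[str, ...] = ("AU54", "AU64", "FaceTouch", "NeckTouch")

#: Codes elevated in the guilt condition (brow lowering, lip stretch,
#: rightward head/eye turns toward the implicated laptop, neck touching).
GUILT_MARKER_AUS: tuple[str, ...] = ("AU4", "AU20", "AU52", "AU62", "NeckTouch")

#: Human-readable FACS names for the codes used in reports.
AU_NAMES: dict[str, str] = {
    "AU1": "Inner Brow Raiser",
    "AU2": "Outer Brow Raiser",
    "AU4": "Brow Lowerer",
    "AU5": "Upper Lid Raiser",
    "AU7": "Lid Tightener",
    "AU10": "Upper Lip Raiser",
    "AU12": "Lip Corner Puller",
    "AU14": "Dimpler",
    "AU17": "Chin Raiser",
    "AU18": "Lip Pucker",
    "AU20": "Lip Stretcher",
    "AU24": "Lip Pressor",
    "AU51": "Head Turn Left",
    "AU52": "Head Turn Right",
    "AU54": "Head Down",
    "AU55": "Head Tilt Left",
    "AU56": "Head Tilt Right",
    "AU57": "Head Forward",
    "AU59": "Head Shake Up Down",
    "AU61": "Eyes Turn Left",
    "AU62": "Eyes Turn Right",
    "AU64": "Eyes Down",
    "FaceTouch": "Face Touch",
    "NeckTouch": "Neck Touch",
}


def validate_codes(codes, ontology=DEFAULT_ONTOLOGY) -> list[str]:
    """Return the unknown codes among *codes* (empty list if all known)."""
    known = set(ontology) | {NOT_VISIBLE}
    return [c for c in codes if c not in known]
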