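"""Item catalogue for the two structured professional judgement instruments.

The risk instrument (HCR-20 v3 layout) has 10 historical items — static,
assessed once at baseline — plus 5 clinical and 5 risk-management items that
are re-rated at every wave.  The protective instrument (SAPROF layout) has 17
dynamic items.  Every item is rated on the same 3-point ordinal scale:
0 = not present, 1 = partially present, 2 = definitely present.

Each item carries a causal ``role`` used by the synthetic cohort generator
and the attenuation analysis:

``static``
    historical items; fixed at baseline, no causal path of their own.
``proximal``
    items that act on violence directly within the concurrent 6-month
    window (violent ideation/intent, instability, stress-or-coping on the
    risk side; self-control on the protective side).
``distal``
    dynamic risk items acting on violence only through the proximal items.
``protective``
    distal protective items, acting only through self-control.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ItemDef", "default_catalogue", "scale_items", "total_score_column"]

SCALES = ("H", "C", "R", "SAPROF")
ROLES = ("static", "distal", "proximal", "protective")


@dataclass(frozen=True)
class ItemDef:
    """One instrument item: identifier, scale membership, display name, causal role."""

    item_id: str
    scale: str  # H, C, R or SAPROF
    name: str
    role: str  # static, distal, proximal or protective

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for item {self.item_id}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for item {self.item_id}")


_H = [
    ("h_violence", "Violence"),
    ("h_antisocial_behaviour", "Other antisocial behaviour"),
    ("h_relationships", "Relationships"),
    ("h_employment", "Employment"),
    ("h_substance_use", "Substance use"),
    ("h_major_mental_disorder", "Major mental disorder"),
    ("h_personality_disorder", "Personality disorder"),
    ("h_traumatic_experiences", "Traumatic experiences"),
    ("h_violent_attitudes", "Violent attitudes"),
    ("h_treatment_response", "Treatment or supervision response"),
]

_C = [
    ("c_insight", "Lack of insight", "distal"),
    ("c_violent_ideation", "Violent ideation or intent", "proximal"),
    ("c_symptoms", "Symptoms of major mental disorder", "distal"),
    ("c_instability", "Instability", "proximal"),
    ("c_treatment_response", "Treatment or supervision response (clinical)", "distal"),
]

_R = [
    ("r_professional_services", "Professional services and plans", "distal"),
    ("r_living_situation", "Living situation", "distal"),
    ("r_personal_support", "Personal support", "distal"),
    ("r_treatment_response", "Treatment or supervision response (risk management)", "distal"),
    ("r_stress_coping", "Stress or coping", "proximal"),
]

_SAPROF = [
    ("s_intelligence", "Intelligence", "protective"),
    ("s_secure_attachment", "Secure attachment in childhood", "protective"),
    ("s_empathy", "Empathy", "protective"),
    ("s_coping", "Coping", "protective"),
    ("s_self_control", "Self-control", "proximal"),
    ("s_work", "Work", "protective"),
    ("s_leisure", "Leisure activities", "protective"),
    ("s_financial", "Financial management", "protective"),
    ("s_motivation", "Motivation for treatment", "protective"),
    ("s_attitudes_authority", "Attitudes towards authority", "protective"),
    ("s_life_goals", "Life goals", "protective"),
    ("s_medication", "Medication", "protective"),
    ("s_social_network", "Social network", "protective"),
    ("s_intimate_relationship", "Intimate relationship", "protective"),
    ("s_professional_care", "Professional care", "protective"),
    ("s_living_circumstances", "Living circumstances", "protective"),
    ("s_external_control", "External control", "protective"),
]


def default_catalogue() -> dict[str, ItemDef]:
    """The full 37-item catalogue keyed by item id, in canonical column order."""
    cat: dict[str, ItemDef] = {}
    for iid, name in _H:
        cat[iid] = ItemDef(iid, "H", name, "static")
    for iid, name, role in _C:
        cat[iid] = ItemDef(iid, "C", name, role)
    for iid, name, role in _R:
        cat[iid] = ItemDef(iid, "R", name, role)
    for iid, name, role in _SAPROF:
        cat[iid] = ItemDef(iid, "SAPROF", name, role)
    return cat


def scale_items(catalogue: dict[str, ItemDef], scale: str) -> list[str]:
    """Item ids belonging to one scale, in catalogue order."""
    return [iid for iid, d in catalogue.items() if d.scale == scale]


def total_score_column(scale: str) -> str:
    """Name of the derived total-score column for a scale."""
    return {"H": "total_h", "C": "total_c", "R": "total_r", "SAPROF": "total_saprof"}[scale]
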