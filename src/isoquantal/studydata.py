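"""Bundled published summaries: triple antiseizure-drug combinations in the
mouse maximal-electroshock (MES) model.

Six 1:1:1 three-drug combinations of lacosamide (LCM) with second-generation
antiseizure medications — lamotrigine (LTG), oxcarbazepine (OXC), pregabalin
(PGB), topiramate (TPM) — were screened in vivo.  For each combination the
published record gives the experimentally fitted mixture ED50 +/- SEM with
its informative-animal count, and the theoretically additive ED50 +/- SEM
with the animal count attached to the additive prediction.  Raw per-dose
protection counts were not published, so these summary rows are the entry
point for re-analysis.

``LITERATURE_TRIPLES`` collects interaction classifications and indices for
further three-drug combinations reported elsewhere in the same assay; they
are display fixtures for polygonogram-style overviews, not quantities this
package recomputes.
"""

from __future__ import annotations

from .data import SummaryEffectRecord

__all__ = ["STUDY_COMBINATIONS", "study_records", "LITERATURE_TRIPLES",
           "STUDY_DRUGS"]

#: drugs appearing in the six bundled combinations
STUDY_DRUGS = ("LCM", "LTG", "OXC", "PGB", "TPM")

#: (label, (ed50_exp, sem_exp, n_exp), (ed50_add, sem_add, n_add))
STUDY_COMBINATIONS: tuple[tuple[str, tuple[float, float, int],
                                tuple[float, float, int]], ...] = (
    ("LCM + OXC + TPM", (31.06, 2.34, 24), (28.25, 3.37, 50)),
    ("LCM + LTG + OXC", (7.50, 0.98, 32), (8.97, 0.51, 42)),
    ("LCM + LTG + PGB", (35.59, 3.86, 24), (45.52, 4.46, 42)),
    ("LCM + LTG + TPM", (19.06, 2.70, 24), (26.47, 3.37, 34)),
    ("LCM + OXC + PGB", (33.04, 4.62, 24), (47.30, 4.45, 58)),
    ("LCM + TPM + PGB", (35.50, 5.28, 24), (64.80, 5.02, 50)),
)


def study_records() -> list[tuple[SummaryEffectRecord, SummaryEffectRecord]]:
    """The six bundled combinations as (experimental, additive) record pairs."""
    out = []
    for label, (e, se, ne), (a, sa, na) in STUDY_COMBINATIONS:
        out.append((SummaryEffectRecord(label, e, se, ne),
                    SummaryEffectRecord(f"{label} (additive)", a, sa, na)))
    return out


#: (combination label, classification, interaction index) from other studies
#: in the same mouse MES assay — polygonogram display fixtures only.
LITERATURE_TRIPLES: tuple[tuple[str, str, float], ...] = (
    ("LCM + CBZ + VPA", "Antagonism", 1.32),
    ("LCM + LTG + VPA", "Antagonism", 1.27),
    ("LCM + CBZ + PB", "Additivity", 1.18),
    ("LCM + LTG + PB", "Additivity", 1.07),
    ("LCM + CBZ + LTG", "Additivity", 1.05),
    ("PB + LTG + OXC", "Additivity", 0.94),
    ("CBZ + PB + VPA", "Additivity", 0.81),
    ("PB + LTG + PGB", "Synergy", 0.64),
    ("PB + OXC + PGB", "Synergy", 0.61),
    ("PB + OXC + TPM", "Synergy", 0.56),
    ("PB + LTG + TPM", "Synergy", 0.56),
    ("PB + PHT + PGB", "Synergy", 0.53),
    ("OXC + PGB + TPM", "Synergy", 0.51),
    ("PB + TPM + PGB", "Synergy", 0.48),
    ("CBZ + PB + TPM", "Synergy", 0.46),
)
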