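"""Published reference values from a large determinant study.

Summary statistics printed in a determinant-selection study of Dutch
citizens' intention to participate in self-led digital contact tracing
(online panel, N=3019 completers): per-determinant and per-cluster mean
scores on the harmonized 1..5 scale, Cohen's d between the positive and
neutral/negative intention groups, and the Potential for Change Index the
authors report for each.  Useful as an arithmetic cross-check of
:func:`behavdet.potential.compute_pci` and as a realistic target profile
for the synthetic generator.

Each row: (cluster, entity, level, mean, d, pci_printed).
"""

from __future__ import annotations

from typing import List, NamedTuple

__all__ = [
    "ReferenceRow",
    "DETERMINANT_TABLE",
    "COUNTS",
    "PRINTED_PERCENTAGES",
]


class ReferenceRow(NamedTuple):
    cluster: str
    entity: str
    level: str          # "item" or "cluster"
    mean: float         # published mean score, 1..5 scale, 2 dp
    d: float            # published Cohen's d, 2 dp
    pci_printed: float  # published PCI, 2 dp


DETERMINANT_TABLE: List[ReferenceRow] = [
    # C1: increased autonomy in contact tracing
    ReferenceRow("C1", "autonomy_sharing_info", "item", 2.15, 0.66, 0.51),
    ReferenceRow("C1", "autonomy_contact_phs", "item", 2.09, 0.60, 0.40),
    ReferenceRow("C1", "cluster", "cluster", 2.12, 0.68, 0.52),
    # C2: ease of digitally participating
    ReferenceRow("C2", "easier_share_info", "item", 2.21, 0.89, 0.96),
    ReferenceRow("C2", "easier_notification", "item", 2.23, 0.83, 0.84),
    ReferenceRow("C2", "easier_identification", "item", 2.17, 0.84, 0.83),
    ReferenceRow("C2", "cluster", "cluster", 2.20, 0.99, 1.20),
    # C3: perceived ability
    ReferenceRow("C3", "own_capacity_identification", "item", 2.13, 0.71, 0.56),
    ReferenceRow("C3", "contacts_informed_digitally", "item", 2.38, 0.55, 0.41),
    ReferenceRow("C3", "cluster", "cluster", 2.25, 0.70, 0.62),
    # C4: general trust in new technologies (singleton)
    ReferenceRow("C4", "trust_new_technologies", "item", 2.42, 1.10, 1.70),
    ReferenceRow("C4", "cluster", "cluster", 2.42, 1.10, 1.70),
    # C5: privacy-related concerns
    ReferenceRow("C5", "bothered_share_personal", "item", 2.86, 0.72, 0.97),
    ReferenceRow("C5", "bothered_reported_by_others", "item", 2.87, 0.66, 0.82),
    ReferenceRow("C5", "feel_watched", "item", 2.85, 0.62, 0.71),
    ReferenceRow("C5", "bothered_share_contacts", "item", 2.68, 0.65, 0.71),
    ReferenceRow("C5", "cluster", "cluster", 2.81, 0.78, 1.10),
    # C6: general attitude toward contact tracing
    ReferenceRow("C6", "general_attitude_ct", "item", 2.09, 0.76, 0.63),
    ReferenceRow("C6", "ct_necessary_population_health", "item", 1.97, 0.76, 0.56),
    ReferenceRow("C6", "cluster", "cluster", 2.03, 0.84, 0.73),
    # C7: attitude toward sharing information
    ReferenceRow("C7", "good_feeling_share_own", "item", 2.74, 0.57, 0.56),
    ReferenceRow("C7", "good_feeling_share_contacts", "item", 3.00, 0.46, 0.43),
    ReferenceRow("C7", "cluster", "cluster", 2.87, 0.55, 0.56),
    # C8: perceived reliability of the public health service (singleton)
    ReferenceRow("C8", "phs_reliable", "item", 2.33, 0.69, 0.63),
    ReferenceRow("C8", "cluster", "cluster", 2.33, 0.69, 0.63),
    # C9: felt responsibility and willingness to cooperate
    ReferenceRow("C9", "overview_with_php", "item", 2.26, 0.85, 0.91),
    ReferenceRow("C9", "duty_to_participate", "item", 2.31, 0.84, 0.91),
    ReferenceRow("C9", "share_contacts_with_php", "item", 2.47, 0.73, 0.79),
    ReferenceRow("C9", "cluster", "cluster", 2.35, 0.89, 1.10),
]

#: Published headline counts: questionnaire starts/completions and, among
#: positive-intention completers, preferences for fully autonomous
#: identification and notification of contacts.
COUNTS = {
    "started": 3170,
    "completed": 3019,
    "positive_intention": 2295,
    "autonomous_identification": 1337,
    "autonomous_notification": 1154,
}

#: The corresponding percentages as printed (completion to 0 dp, the
#: intention prevalence to 0 dp, the preference shares to 1 dp).
PRINTED_PERCENTAGES = {
    "completion_rate": 95.0,
    "positive_intention": 76.0,
    "autonomous_identification": 58.3,
    "autonomous_notification": 50.3,
}
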