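"""Published species-percentage decompositions used as simulation inputs.

Two panels of rAAV6 preps: HEK293T triple-transfection preps (1, 2, 5, 6)
and Sf9/baculovirus preps (3, 4), each sequenced with and without DNase
pretreatment. Values are percentages of deduplicated reads per DNA species;
``unmapped`` is everything that matched no known reference. Columns do not
sum to exactly 100 as printed; :func:`composition_fractions` renormalizes.
"""

from __future__ import annotations

from .simulate import PrepSpec

# prep -> dnase(False/True) -> species -> percent
HEK293T_PREPS: dict[str, dict[bool, dict[str, float]]] = {
    "prep1": {
        False: {"rAAV_genome": 1.08, "producer_genome": 86.41, "helper_plasmid": 1.55,
                "plasmid_backbone": 0.21, "repcap_plasmid": 0.33, "ecoli_genome": 1.06,
                "unmapped": 9.56},
        True: {"rAAV_genome": 1.18, "producer_genome": 85.36, "helper_plasmid": 1.25,
               "plasmid_backbone": 0.21, "repcap_plasmid": 0.35, "ecoli_genome": 0.97,
               "unmapped": 10.38},
    },
    "prep2": {
        False: {"rAAV_genome": 45.02, "producer_genome": 26.42, "helper_plasmid": 1.24,
                "plasmid_backbone": 0.65, "repcap_plasmid": 0.24, "ecoli_genome": 2.13,
                "unmapped": 24.40},
        True: {"rAAV_genome": 83.91, "producer_genome": 8.64, "helper_plasmid": 1.17,
               "plasmid_backbone": 0.83, "repcap_plasmid": 0.16, "ecoli_genome": 0.87,
               "unmapped": 4.43},
    },
    "prep5": {
        False: {"rAAV_genome": 69.26, "producer_genome": 0.47, "helper_plasmid": 3.27,
                "plasmid_backbone": 0.47, "repcap_plasmid": 0.17, "ecoli_genome": 1.79,
                "unmapped": 24.58},
        True: {"rAAV_genome": 84.15, "producer_genome": 0.48, "helper_plasmid": 3.64,
               "plasmid_backbone": 0.52, "repcap_plasmid": 0.18, "ecoli_genome": 1.47,
               "unmapped": 9.57},
    },
    "prep6": {
        False: {"rAAV_genome": 68.22, "producer_genome": 1.97, "helper_plasmid": 3.01,
                "plasmid_backbone": 2.77, "repcap_plasmid": 0.16, "ecoli_genome": 2.33,
                "unmapped": 21.54},
        True: {"rAAV_genome": 88.11, "producer_genome": 0.39, "helper_plasmid": 4.28,
               "plasmid_backbone": 3.94, "repcap_plasmid": 0.25, "ecoli_genome": 0.67,
               "unmapped": 2.36},
    },
}

SF9_PREPS: dict[str, dict[bool, dict[str, float]]] = {
    "prep3": {
        False: {"rAAV_genome": 80.75, "producer_genome": 0.07, "baculovirus": 0.20,
                "plasmid_backbone": 0.77, "repcap_plasmid": 0.005, "ecoli_genome": 0.73,
                "unmapped": 17.48},
        True: {"rAAV_genome": 91.99, "producer_genome": 0.052, "baculovirus": 0.15,
               "plasmid_backbone": 0.68, "repcap_plasmid": 0.002, "ecoli_genome": 0.61,
               "unmapped": 6.51},
    },
    "prep4": {
        False: {"rAAV_genome": 95.67, "producer_genome": 0.22, "baculovirus": 0.29,
                "plasmid_backbone": 0.13, "repcap_plasmid": 0.0052, "ecoli_genome": 0.83,
                "unmapped": 2.85},
        True: {"rAAV_genome": 94.85, "producer_genome": 0.20, "baculovirus": 0.42,
               "plasmid_backbone": 0.16, "repcap_plasmid": 0.0066, "ecoli_genome": 0.47,
               "unmapped": 3.89},
    },
}

ALL_PREPS = {**HEK293T_PREPS, **SF9_PREPS}

#: %rAAV genome purity per prep without DNase pretreatment (the regression x).
PURITY_MINUS_DNASE = {p: cols[False]["rAAV_genome"] for p, cols in ALL_PREPS.items()}
PURITY_PLUS_DNASE = {p: cols[True]["rAAV_genome"] for p, cols in ALL_PREPS.items()}


def composition_fractions(prep: str, dnase: bool) -> dict[str, float]:
    """Printed column scaled to sum exactly 1, with ``unmapped`` relabelled
    ``foreign`` (the simulator's stand-in for the unmapped bucket)."""
    col = ALL_PREPS[prep][dnase]
    total = sum(col.values())
    out = {}
    for sp, pct in col.items():
        out["foreign" if sp == "unmapped" else sp] = pct / total
    return out


def prep_spec_from_table(prep: str, dnase: bool, **kwargs) -> PrepSpec:
    """PrepSpec whose composition is the printed column for (prep, dnase)."""
    return PrepSpec(prep_id=prep, fractions=composition_fractions(prep, dnase), **kwargs)
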