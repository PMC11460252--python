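"""DNase-differential localization: extra- vs intra-capsid contaminants.

Sequencing a prep with and without DNase pretreatment separates protected
(encapsidated) DNA from unprotected DNA. Because removing extra-capsid DNA
mechanically inflates every surviving species' raw percentage, each
contaminant's share is first normalized to the rAAV-genome share (the
protected yardstick); the log2 change of that ratio across the +/-DNase
pair then reads directly as susceptibility: a drop of at least 2-fold calls
the species extra-capsid, anything less is intra-capsid.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

from .classify import SpeciesProfile

EXTRA_CAPSID = "extra_capsid"
INTRA_CAPSID = "intra_capsid"
INDETERMINATE = "indeterminate"


@dataclass
class LocalizationCall:
    species_label: str
    ratio_minus: float | None   # species% / rAAV% without DNase
    ratio_plus: float | None    # with DNase
    log2_change: float | None
    verdict: str


def localize(
    profile_minus: SpeciesProfile,
    profile_plus: SpeciesProfile,
    floor: float = 0.01,
) -> list[LocalizationCall]:
    """Per-species localization verdicts from a -/+DNase profile pair.

    ``floor`` is in percentage points: a species below it in both profiles
    carries no signal and is called indeterminate. Verdicts: extra_capsid
    when log2_change <= -1, intra_capsid when |log2_change| < 1, otherwise
    indeterminate (undefined ratios, or an apparent >=2-fold relative
    enrichment, which the susceptibility model does not produce).
    """
    if profile_minus.prep_id != profile_plus.prep_id:
        raise ValueError(
            f"profiles are from different preps: "
            f"{profile_minus.prep_id!r} vs {profile_plus.prep_id!r}"
        )
    if profile_minus.dnase or not profile_plus.dnase:
        raise ValueError("expected (dnase=False, dnase=True) profile pair")
    raav_minus = profile_minus.percentages.get("rAAV_genome", 0.0)
    raav_plus = profile_plus.percentages.get("rAAV_genome", 0.0)
    if raav_minus <= 0 or raav_plus <= 0:
        raise ValueError("rAAV genome percentage is zero in a profile")

    calls = []
    for sp in profile_minus.percentages:
        if sp == "rAAV_genome":
            continue
        pm = profile_minus.percentages.get(sp, 0.0)
        pp = profile_plus.percentages.get(sp, 0.0)
        if pm < floor and pp < floor:
            calls.append(LocalizationCall(sp, None, None, None, INDETERMINATE))
            continue
        ratio_minus = pm / raav_minus
        ratio_plus = pp / raav_plus
        if ratio_minus <= 0 or ratio_plus <= 0:
            calls.append(
                LocalizationCall(
                    sp,
                    ratio_minus if ratio_minus > 0 else None,
                    ratio_plus if ratio_plus > 0 else None,
                    None,
                    INDETERMINATE,
                )
            )
            continue
        change = log2(ratio_plus / ratio_minus)
        if change <= -1.0:
            verdict = EXTRA_CAPSID
        elif abs(change) < 1.0:
            verdict = INTRA_CAPSID
        else:
            verdict = INDETERMINATE
        calls.append(LocalizationCall(sp, ratio_minus, ratio_plus, change, verdict))
    return calls


def spike_qc(
    control_minus,
    control_plus,
    max_survival: float = 0.01,
) -> bool:
    """Digestion control: lambda spike-in must be (almost) fully destroyed.

    ``control_minus``/``control_plus`` are the lambda-only control runs,
    given either as molecule counts or as :class:`SpeciesProfile` objects
    (whose deduplicated totals are used). Passes when the +DNase lambda
    molecule count is at most ``max_survival`` times the -DNase count.
    """

    def count(c):
        if isinstance(c, SpeciesProfile):
            return c.n_total_dedup * c.percentages.get("lambda_spike", 0.0) / 100.0
        return float(c)

    n_minus = count(control_minus)
    n_plus = count(control_plus)
    if n_minus <= 0:
        raise ValueError("-DNase lambda control has zero molecules")
    return n_plus <= max_survival * n_minus
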