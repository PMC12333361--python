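"""Kaptein sign rules and radical-pair mechanism assignment.

Phenolic targets can form their radical either by direct electron transfer
(ET) or by proton-coupled electron transfer (PCET); the two radicals have
different g-factors and hyperfine couplings and therefore predict
different polarization phases. Kaptein's net-effect rule

    Gamma_net = mu * eps * sign(dg) * sign(a_iso)

(+1 absorptive, -1 emissive; mu = precursor multiplicity, eps = product
channel) lets us predict the phase for each candidate radical and pick
the mechanism whose predictions agree best with the observed signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .config import PipelineConfig
from .features import geminate_polarization_q
from .records import MoleculeRecord, RadicalHypothesis


def kaptein_net_sign(mu: int, eps: int, delta_g_signed: float, a_iso_signed: float) -> int:
    """Net-effect Kaptein rule: the product of the four signs.

    Returns +1 (absorptive), -1 (emissive) or 0 when either the g-factor
    difference or the hyperfine coupling vanishes. Multiplicative in each
    argument's sign.
    """
    if mu not in (+1, -1) or eps not in (+1, -1):
        raise ValueError("mu and eps must be +1 or -1")
    if delta_g_signed == 0 or a_iso_signed == 0:
        return 0
    sign_dg = 1 if delta_g_signed > 0 else -1
    sign_a = 1 if a_iso_signed > 0 else -1
    return mu * eps * sign_dg * sign_a


@dataclass
class MechanismAssignment:
    """Outcome of comparing candidate radicals against observation."""

    molecule_id: str
    chosen: str  # "ET", "PCET" or "ambiguous"
    per_site_predicted_sign: dict[str, dict[str, int]]  # mechanism -> site -> sign
    agreement_fraction: dict[str, float]  # mechanism -> fraction in [0, 1]
    chosen_hypothesis: Optional[RadicalHypothesis] = field(default=None, repr=False)


class UnresolvedMechanismError(ValueError):
    """The assignment was ambiguous; features cannot be finalized."""


def assign_mechanism(
    molecule_id: str,
    hypotheses: list[RadicalHypothesis],
    observed_signs: Mapping[str, int],
    g_dye: float,
    mu: int = +1,
    eps: int = +1,
) -> MechanismAssignment:
    """Choose the mechanism whose Kaptein-predicted signs best match
    the observed per-site polarization phases.

    ``mu`` defaults to +1 (triplet precursor, the usual case for xanthene
    dyes) and ``eps`` to +1 (polarization observed on the regenerated
    diamagnetic molecule, i.e. the recombination product). The signed
    g-factor difference is taken as g_dye - g_radical. Ties are reported
    as ``ambiguous``, never silently broken.
    """
    if not hypotheses:
        raise ValueError(f"{molecule_id}: no radical hypotheses supplied")
    if not observed_signs:
        raise ValueError(f"{molecule_id}: no observed site signs supplied")
    mechs = [h.mechanism for h in hypotheses]
    if len(set(mechs)) != len(mechs):
        raise ValueError(f"{molecule_id}: duplicate mechanism labels {mechs}")

    predicted: dict[str, dict[str, int]] = {}
    agreement: dict[str, float] = {}
    for hyp in hypotheses:
        dg = g_dye - hyp.g_radical
        signs = {
            site: kaptein_net_sign(mu, eps, dg, a)
            for site, a in hyp.a_iso_by_site.items()
        }
        predicted[hyp.mechanism] = signs
        common = [s for s in observed_signs if s in signs]
        if not common:
            raise ValueError(
                f"{molecule_id}: hypothesis {hyp.mechanism} shares no sites with observations"
            )
        agreement[hyp.mechanism] = sum(
            1 for s in common if signs[s] == observed_signs[s]
        ) / len(common)

    best = max(agreement.values())
    winners = [m for m, a in agreement.items() if a == best]
    if len(winners) > 1:
        return MechanismAssignment(molecule_id, "ambiguous", predicted, agreement, None)
    chosen = winners[0]
    chosen_hyp = next(h for h in hypotheses if h.mechanism == chosen)
    return MechanismAssignment(molecule_id, chosen, predicted, agreement, chosen_hyp)


def select_radical_features(
    molecule: MoleculeRecord,
    assignment: MechanismAssignment,
    config: PipelineConfig,
) -> MoleculeRecord:
    """Install the chosen radical's parameters into the molecule record.

    Replaces each site's a_iso with the chosen hypothesis's value, sets
    delta_g = |g_dye - g_radical| and recomputes Q (stored at the
    configured scale). Idempotent: applying the same assignment twice is
    a no-op the second time.
    """
    if assignment.chosen not in ("ET", "PCET") or assignment.chosen_hypothesis is None:
        raise UnresolvedMechanismError(
            f"{molecule.molecule_id}: mechanism is {assignment.chosen!r}; "
            "resolve the ambiguity (check the observed signs) before selecting features"
        )
    hyp = assignment.chosen_hypothesis
    from dataclasses import replace

    delta_g = abs(config.g_dye - hyp.g_radical)
    new_sites = []
    for site in molecule.sites:
        if site.site_id not in hyp.a_iso_by_site:
            raise KeyError(
                f"{molecule.molecule_id}: hypothesis {hyp.mechanism} has no a_iso for site {site.site_id!r}"
            )
        a = hyp.a_iso_by_site[site.site_id]
        q = geminate_polarization_q(abs(a), config.g_dye, config.g_dye - delta_g, config.b0)
        new_sites.append(replace(site, a_iso=a, q_value=q / config.q_scale))
    return replace(molecule, sites=new_sites, delta_g=delta_g, mechanism=assignment.chosen)
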