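"""Synthetic compound libraries with planted ground truth.

The generator emulates the statistical structure of a steady-state
photo-CIDNP screening data set — a library of indole, amino-acid and
phenol derivatives measured against one dye — so that every pipeline
stage can be exercised and validated without any experimental data:

* family-level logP, molecule-level IP with a nucleophilicity index
  anticorrelated and a LUMO-HOMO gap positively correlated with it;
* site-level Fukui indices drawn from a Dirichlet (summing to 1 per
  molecule), hyperfine couplings linearly coupled to Fukui with Gaussian
  noise, and Q computed through the same formula the features module
  uses;
* a latent SNE that is Fukui-dominant within a molecule, depends
  quadratically (Marcus-like) on the ionization potential between
  molecules, and carries multiplicative lognormal noise plus a detection
  floor;
* an exact, planted within-molecule concordance: a per-molecule Bernoulli
  draw decides whether the max-SNE site coincides with the max-Fukui
  site, so argmax recovery experiments are controlled binomial trials.

Every latent quantity is recorded in a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .constants import Q_SCALE
from .features import geminate_polarization_q
from .records import FeatureTable

#: Library composition mirroring a realistic screening campaign:
#: many indole derivatives, a few amino acids and phenols.
DEFAULT_FAMILY_SIZES = {"indole": 27, "amino_acid": 5, "phenol": 8}

# family-level centers for molecule-level features
_FAMILY_SNE_SCALE = {"indole": 260.0, "amino_acid": 55.0, "phenol": 75.0}
_FAMILY_LOGP_MEAN = {"indole": 2.1, "amino_acid": -1.0, "phenol": 1.5}
_SERIES_CODES = {"indole": ("H", "M", "N", "O"), "amino_acid": ("A",), "phenol": ("P", "Q")}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic library; defaults are the study conditions.

    ``concordance`` is the probability that, within a molecule, the
    max-SNE site coincides with the max-Fukui site (enforced exactly).
    ``kappa``/``sigma_a`` set the linear Fukui -> a_iso coupling and its
    Gaussian noise; ``marcus_lambda``/``ip_optimum`` the quadratic
    (inverted-parabola) dependence of the molecular SNE scale on IP.
    """

    family_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FAMILY_SIZES))
    sites_min: int = 3
    sites_max: int = 7
    fukui_dirichlet_alpha: float = 0.8
    kappa: float = 90.0  # MHz per unit Fukui
    sigma_a: float = 6.0  # MHz
    ip_mean: float = 7.5  # eV
    ip_sd: float = 0.6  # eV
    ip_optimum: float = 7.3  # eV
    marcus_lambda: float = 0.6  # eV^-2
    delta_g_median: float = 1.5e-3
    delta_g_sigma: float = 0.4  # lognormal sigma
    gamma: float = 1.0  # Fukui exponent in the latent SNE
    molecule_scale_sigma: float = 0.5  # lognormal sigma of per-molecule scale
    sne_noise_sigma: float = 0.25  # lognormal sigma of per-site noise
    detection_floor: float = 1.0  # SNE below this reads as the floor
    concordance: float = 0.925
    amino_series_attenuation: float = 0.25  # multiplier for the charged "N" series
    log_p_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sites_min < 2 or self.sites_max < self.sites_min:
            raise ValueError("need sites_max >= sites_min >= 2")
        for name in ("sigma_a", "molecule_scale_sigma", "sne_noise_sigma", "delta_g_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0, 1]")
        if any(n < 1 for n in self.family_sizes.values()):
            raise ValueError("every family needs at least one molecule")


def generate_library(
    params: GeneratorParams | None = None, config: PipelineConfig | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate one synthetic library and its ground truth.

    Returns ``(table, ground_truth)`` where the ground-truth frame holds,
    per site, the latent noise-free SNE, the planted max-SNE site flag and
    whether the molecule was planted as Fukui-concordant. Bit-identical
    for a fixed ``params.seed``.
    """
    params = params or GeneratorParams()
    config = config or PipelineConfig()
    rng = np.random.default_rng(params.seed)

    mol_rows = []
    for family, n_mol in params.family_sizes.items():
        series_pool = _SERIES_CODES.get(family, ("X",))
        for i in range(n_mol):
            mol_rows.append((f"{family[:3].upper()}{i + 1:02d}", family, series_pool[i % len(series_pool)]))
    n_molecules = len(mol_rows)

    # molecule-level features
    ip = rng.normal(params.ip_mean, params.ip_sd, n_molecules)
    nucleophilicity = 10.2 - 0.9 * ip + rng.normal(0, 0.15, n_molecules)
    lumo_homo = -1.8 + 0.75 * ip + rng.normal(0, 0.2, n_molecules)
    delta_g = params.delta_g_median * np.exp(rng.normal(0, params.delta_g_sigma, n_molecules))
    families = np.array([r[1] for r in mol_rows])
    series = np.array([r[2] for r in mol_rows])
    # logP is a family/series-level property: one draw per (family, series)
    log_p_by_group = {}
    log_p = np.empty(n_molecules)
    for i, (fam, ser) in enumerate(zip(families, series)):
        key = (fam, ser)
        if key not in log_p_by_group:
            log_p_by_group[key] = rng.normal(_FAMILY_LOGP_MEAN[fam], params.log_p_sd)
        log_p[i] = log_p_by_group[key]

    n_sites = rng.integers(params.sites_min, params.sites_max + 1, n_molecules)
    total = int(n_sites.sum())
    mol_index = np.repeat(np.arange(n_molecules), n_sites)
    starts = np.concatenate([[0], np.cumsum(n_sites)[:-1]])

    # site-level: Dirichlet Fukui via normalized Gamma draws
    gamma_draws = rng.gamma(params.fukui_dirichlet_alpha, 1.0, total)
    sums = np.add.reduceat(gamma_draws, starts)
    fukui = gamma_draws / sums[mol_index]
    a_iso = params.kappa * fukui + rng.normal(0, params.sigma_a, total)
    q = geminate_polarization_q(
        np.abs(a_iso), config.g_dye, config.g_dye - delta_g[mol_index], config.b0
    ) / config.q_scale

    # latent SNE: molecule scale x Marcus-like IP factor x Fukui dominance
    fam_scale = np.array([_FAMILY_SNE_SCALE[f] for f in families])
    atten = np.where(series == "N", params.amino_series_attenuation, 1.0)
    mol_scale = (
        fam_scale
        * atten
        * np.exp(-params.marcus_lambda * (ip - params.ip_optimum) ** 2)
        * np.exp(rng.normal(0, params.molecule_scale_sigma, n_molecules))
    )
    latent = mol_scale[mol_index] * fukui**params.gamma
    sne = latent * np.exp(rng.normal(0, params.sne_noise_sigma, total))
    sne = np.maximum(sne, params.detection_floor)

    # plant the within-molecule concordance exactly
    concordant = rng.random(n_molecules) < params.concordance
    for m in range(n_molecules):
        s, e = starts[m], starts[m] + n_sites[m]
        f_arg = s + int(np.argmax(fukui[s:e]))
        s_arg = s + int(np.argmax(sne[s:e]))
        if concordant[m]:
            if s_arg != f_arg:
                sne[s_arg], sne[f_arg] = sne[f_arg], sne[s_arg]
        else:
            others = [j for j in range(s, e) if j != f_arg]
            target = others[int(rng.integers(len(others)))]
            s_arg = s + int(np.argmax(sne[s:e]))
            if s_arg != target:
                sne[s_arg], sne[target] = sne[target], sne[s_arg]
            if sne[target] <= sne[f_arg]:  # guarantee a strict miss
                sne[target] = sne[f_arg] * 1.05 + 1.0

    site_ids = np.concatenate([np.arange(1, k + 1).astype(str) for k in n_sites])
    mol_ids = np.array([r[0] for r in mol_rows])
    frame = pd.DataFrame(
        {
            "molecule_id": mol_ids[mol_index],
            "family": families[mol_index],
            "series": series[mol_index],
            "site_id": site_ids,
            "ip": ip[mol_index],
            "nucleophilicity": nucleophilicity[mol_index],
            "lumo_homo": lumo_homo[mol_index],
            "delta_g": delta_g[mol_index],
            "a_iso": a_iso,
            "fukui": fukui,
            "q_value": q,
            "log_p": log_p[mol_index],
            "sne": sne,
        }
    )
    max_flag = np.zeros(total, dtype=bool)
    for m in range(n_molecules):
        s, e = starts[m], starts[m] + n_sites[m]
        max_flag[s + int(np.argmax(sne[s:e]))] = True
    truth = pd.DataFrame(
        {
            "molecule_id": mol_ids[mol_index],
            "site_id": site_ids,
            "latent_sne": latent,
            "molecule_scale": mol_scale[mol_index],
            "is_max_sne_site": max_flag,
            "planted_concordant": concordant[mol_index],
        }
    )
    table = FeatureTable(
        frame, {"q_scale": config.q_scale, "b0": config.b0, "g_dye": config.g_dye, "seed": params.seed}
    )
    return table, truth


def _class_counts(n_sites: int, proportions: tuple[float, ...]) -> list[int]:
    """Exact class counts from proportions.

    Floors each product, then hands leftover units to classes in
    descending-proportion order — e.g. (0.75, 0.21, 0.04) on 190 sites
    gives (143, 40, 7).
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {proportions}")
    raw = [p * n_sites for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    leftover = n_sites - sum(counts)
    order = np.argsort(proportions)[::-1]
    for k in range(leftover):
        counts[int(order[k % len(order)])] += 1
    if any(c < 1 for c in counts):
        raise ValueError(f"infeasible class counts {counts} for {n_sites} sites")
    return counts


def generate_class_structured(
    params: GeneratorParams | None = None,
    class_proportions: tuple[float, float, float] = (0.75, 0.21, 0.04),
    n_sites: int = 190,
    separation: float = 1.5,
    thresholds: tuple[float, float] = (40.0, 90.0),
    seed: int | None = None,
) -> FeatureTable:
    """Library whose SNE marginal hits the requested class counts exactly.

    SNE values are drawn uniformly inside each class band (low / medium /
    high under ``thresholds``); features are drawn with class-dependent
    mean shifts of ``separation`` standard deviations between adjacent
    classes, weighted toward the features that plausibly carry class
    information (logP, delta_g, Fukui). ``separation=0`` makes features
    uninformative (classifier accuracy collapses to the class prior);
    large separations make classes linearly separable.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    counts = _class_counts(n_sites, class_proportions)
    low_upper, high_lower = thresholds

    cls = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    rng.shuffle(cls)
    bands = [(params.detection_floor, low_upper), (low_upper, high_lower), (high_lower, high_lower * 4)]
    sne = np.array([rng.uniform(*bands[c]) for c in cls])

    # per-feature class-shift weights (which features carry the signal)
    weights = {
        "ip": -0.3, "nucleophilicity": 0.3, "lumo_homo": -0.3,
        "delta_g": 1.0, "a_iso": 0.5, "fukui": 1.0, "q_value": 0.8, "log_p": 1.0,
    }
    base = {
        "ip": (7.5, 0.6), "nucleophilicity": (3.0, 0.5), "lumo_homo": (3.8, 0.5),
        "a_iso": (25.0, 10.0), "fukui": (0.2, 0.08), "log_p": (1.5, 1.0),
    }
    cols = {}
    for name, (mu0, sd) in base.items():
        cols[name] = rng.normal(mu0 + separation * sd * weights[name] * cls, sd)
    # positivity-constrained features: shift in log space
    cols["delta_g"] = np.exp(rng.normal(np.log(1.5e-3) + separation * 0.3 * weights["delta_g"] * cls, 0.3))
    cols["q_value"] = np.exp(rng.normal(np.log(2.0) + separation * 0.3 * weights["q_value"] * cls, 0.3))

    sites_per_mol = 5
    n_mol = int(np.ceil(n_sites / sites_per_mol))
    mol_index = np.arange(n_sites) // sites_per_mol
    fam_cycle = np.array(["indole", "amino_acid", "phenol"])
    frame = pd.DataFrame(
        {
            "molecule_id": [f"SYN{m + 1:03d}" for m in mol_index],
            "family": fam_cycle[mol_index % 3],
            "series": "S",
            "site_id": (np.arange(n_sites) % sites_per_mol + 1).astype(str),
            **{k: cols[k] for k in ("ip", "nucleophilicity", "lumo_homo", "delta_g", "a_iso", "fukui", "q_value", "log_p")},
            "sne": sne,
        }
    )
    assert n_mol == frame["molecule_id"].nunique()
    return FeatureTable(frame, {"q_scale": Q_SCALE, "class_counts": counts, "separation": separation})


def generate_mechanism_truth(
    n_molecules: int = 500,
    n_sites: int = 5,
    flip_rate: float = 0.1,
    g_dye: float = 2.0034,
    seed: int = 0,
):
    """Planted-truth fixtures for mechanism assignment.

    For each molecule, builds an ET and a PCET radical hypothesis whose
    g-factors sit on opposite sides of the dye's (the physically salient
    difference between the two radicals), shared signed hyperfine
    patterns, picks one as the truth, and emits observed signs equal to
    the true hypothesis's Kaptein predictions with each site's sign
    flipped independently at ``flip_rate``.

    Returns a list of ``(hypotheses, observed_signs, true_mechanism)``.
    """
    from .mechanism import kaptein_net_sign
    from .records import RadicalHypothesis

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_molecules):
        site_ids = [str(i + 1) for i in range(n_sites)]
        a_pattern = rng.uniform(2.0, 60.0, n_sites) * rng.choice([-1, 1], n_sites)
        g_lo = g_dye - rng.uniform(5e-4, 3e-3)
        g_hi = g_dye + rng.uniform(5e-4, 3e-3)
        hyps = [
            RadicalHypothesis("ET", g_lo, dict(zip(site_ids, a_pattern))),
            RadicalHypothesis("PCET", g_hi, dict(zip(site_ids, a_pattern))),
        ]
        true = hyps[int(rng.integers(2))]
        dg = g_dye - true.g_radical
        observed = {}
        for s in site_ids:
            sign = kaptein_net_sign(+1, +1, dg, true.a_iso_by_site[s])
            if rng.random() < flip_rate:
                sign = -sign
            observed[s] = sign
        out.append((hyps, observed, true.mechanism))
    return out
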