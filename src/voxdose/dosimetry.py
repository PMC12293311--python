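"""Organ absorbed dose and effective dose from heating tallies.

The chain is the standard external-dosimetry one: a heating tally gives
deposited energy per organ in eV per source particle; dividing by the
organ mass and converting units yields the absorbed dose D_T (pGy per
particle); normalising by the fluence recorded on a plane outside the
phantom turns it into a fluence-to-dose conversion coefficient DCC
(pGy cm^2); weighting equivalent doses with the ICRP-103 tissue
weighting factors w_T (photon radiation weighting factor w_R = 1, so
numerically pSv = pGy) gives the effective dose

    ED = sum_T w_T H_T + w_rem * mean(H_T over remainder tissues).

The remainder term uses the arithmetic mean of the remainder organ
equivalent doses, the ICRP-103 convention.  Uncertainties propagate in
quadrature assuming independent organ tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import VoxelPhantom
from .transport import FluenceTally, HeatingTally

#: electron volts to joules
C1_J_PER_EV = 1.602176634e-19
#: grays to picograys
C2_PGY_PER_GY = 1.0e12


@dataclass(frozen=True)
class TissueWeights:
    """ICRP-style tissue weighting factors.

    ``weights`` maps the named organs to w_T; ``remainder_weight`` is
    shared by the ``remainder_organs`` via their arithmetic mean;
    ``organ_groups`` maps a weighted-organ name onto several registry
    organ names whose doses are combined mass-weighted (used for the
    colon, segmented as upper + lower).
    """

    weights: dict[str, float]
    remainder_weight: float
    remainder_organs: tuple[str, ...]
    w_r_photon: float = 1.0
    organ_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.weights.values()) + self.remainder_weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue weights sum to {total}, expected exactly 1")
        if any(w <= 0 for w in self.weights.values()) or self.remainder_weight < 0:
            raise ValueError("tissue weighting factors must be positive")


def icrp103_weights() -> TissueWeights:
    """Default ICRP-103 weighting: 14 named organs plus a 0.12 remainder."""
    return TissueWeights(
        weights={
            "red_marrow": 0.12, "colon": 0.12, "lungs": 0.12, "stomach": 0.12,
            "breast": 0.12, "gonads": 0.08, "bladder": 0.04, "oesophagus": 0.04,
            "liver": 0.04, "thyroid": 0.04, "bone_surface": 0.01, "brain": 0.01,
            "salivary_glands": 0.01, "skin": 0.01,
        },
        remainder_weight=0.12,
        remainder_organs=(
            "adrenals", "extrathoracic", "gall_bladder", "heart", "kidneys",
            "lymph_nodes", "muscle", "oral_mucosa", "pancreas", "prostate",
            "small_intestine", "spleen", "thymus",
        ),
        organ_groups={"colon": ("colon_upper", "colon_lower")},
    )


def heating_to_dose(tally: HeatingTally, masses_kg: dict[int, float]):
    """Absorbed dose per organ: D_T = heating_eV * C1 / mass_kg * C2 (pGy).

    ``masses_kg`` maps organ ID to mass in kilograms.  Returns two dicts
    (dose, uncertainty) keyed by organ ID, in pGy per source particle.
    """
    dose, unc = {}, {}
    for oid, ev in tally.heating_ev.items():
        if oid not in masses_kg:
            raise KeyError(f"no mass given for tallied organ ID {oid}")
        m = masses_kg[oid]
        if m <= 0:
            if ev == 0:
                dose[oid], unc[oid] = 0.0, 0.0
                continue
            raise ValueError(f"organ ID {oid} has non-positive mass {m}")
        f = C1_J_PER_EV / m * C2_PGY_PER_GY
        dose[oid] = ev * f
        unc[oid] = tally.sem_ev.get(oid, 0.0) * f
    return dose, unc


def normalize_to_fluence(dose_per_particle, fluence: FluenceTally):
    """Fluence-to-dose conversion coefficients DCC = D / phi (pGy cm^2).

    Accepts a scalar or a dict of doses per source particle; relative
    fluence uncertainty propagates in quadrature when given.
    """
    if fluence.per_particle <= 0:
        raise ZeroDivisionError("fluence must be positive to normalise doses")
    if isinstance(dose_per_particle, dict):
        return {k: v / fluence.per_particle for k, v in dose_per_particle.items()}
    return dose_per_particle / fluence.per_particle


def phantom_masses_kg(phantom: VoxelPhantom) -> dict[int, float]:
    """Organ masses in kilograms keyed by organ ID."""
    counts = phantom.organ_voxel_counts()
    return {
        o.id: counts.get(o.id, 0) * phantom.pitch**3 * o.density / 1000.0
        for o in phantom.registry
    }


def effective_dose(doses: dict[str, float], weights: TissueWeights,
                   uncertainties: dict[str, float] | None = None,
                   masses: dict[str, float] | None = None):
    """Effective dose from per-organ doses (any per-fluence or
    per-particle normalisation; ED inherits it, pSv for photons).

    ``doses`` is keyed by organ name.  Weighted organs listed in
    ``organ_groups`` may be present under their member names instead;
    their doses combine mass-weighted (``masses`` required, same keys).
    Returns ``(ed, ed_uncertainty)``.
    """
    uncertainties = uncertainties or {}

    def organ_dose(name):
        if name in doses:
            return doses[name], uncertainties.get(name, 0.0)
        if name in weights.organ_groups:
            members = [m for m in weights.organ_groups[name] if m in doses]
            if not members:
                return None
            if masses:
                w = np.array([masses.get(m, 0.0) for m in members])
                if w.sum() == 0:
                    w = np.ones(len(members))
            else:
                w = np.ones(len(members))
            w = w / w.sum()
            d = sum(wi * doses[m] for wi, m in zip(w, members))
            u = np.sqrt(sum((wi * uncertainties.get(m, 0.0)) ** 2
                            for wi, m in zip(w, members)))
            return d, u
        return None

    ed, var = 0.0, 0.0
    missing = []
    for name, w_t in weights.weights.items():
        got = organ_dose(name)
        if got is None:
            missing.append(name)
            continue
        d, u = got
        h = weights.w_r_photon * d
        ed += w_t * h
        var += (w_t * weights.w_r_photon * u) ** 2
    if missing:
        raise KeyError(f"weighted organs missing from dose table: {missing}")

    if weights.remainder_weight > 0:
        rem = [(doses[n], uncertainties.get(n, 0.0))
               for n in weights.remainder_organs if n in doses]
        if not rem:
            raise ValueError("remainder weight > 0 but no remainder organ doses")
        k = len(rem)
        ed += weights.remainder_weight * weights.w_r_photon * sum(
            d for d, _ in rem) / k
        var += sum(
            (weights.remainder_weight * weights.w_r_photon * u / k) ** 2
            for _, u in rem)
    return ed, float(np.sqrt(var))


# ----------------------------------------------------------------------
# Tables over an energy grid

def compute_organ_dose_table(phantom: VoxelPhantom, energies_mev,
                             engine: str = "kerma", n: int = 100_000,
                             seed: int = 0, batches: int = 10,
                             table=None, source_factory=None):
    """Organ DCC table (pGy cm^2) over an energy grid.

    ``engine`` is ``"kerma"`` (deterministic, zero variance) or ``"mc"``.
    Returns ``(dose_df, unc_df)``: organs (by name) x energies.
    ``source_factory(phantom, energy)`` defaults to the AP broad beam.
    """
    from .transport import ap_source, deposit_kerma, mc_transport

    source_factory = source_factory or ap_source
    masses = phantom_masses_kg(phantom)
    names = {o.id: o.name for o in phantom.registry}
    dose_cols, unc_cols = {}, {}
    for e in energies_mev:
        src = source_factory(phantom, e)
        if engine == "kerma":
            tally, fl = deposit_kerma(phantom, src, table=table)
        elif engine == "mc":
            tally, fl = mc_transport(phantom, src, n=n, seed=seed,
                                     batches=batches, table=table)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        d, u = heating_to_dose(tally, masses)
        dcc = normalize_to_fluence(d, fl)
        ucc = normalize_to_fluence(u, fl)
        dose_cols[e] = {names[k]: v for k, v in dcc.items()}
        unc_cols[e] = {names[k]: v for k, v in ucc.items()}
    dose_df = pd.DataFrame(dose_cols)
    unc_df = pd.DataFrame(unc_cols).reindex(index=dose_df.index)
    return dose_df, unc_df


def effective_dose_table(dose_df: pd.DataFrame, unc_df: pd.DataFrame | None = None,
                         weights: TissueWeights | None = None,
                         masses: dict[str, float] | None = None) -> pd.DataFrame:
    """ED(E) with uncertainty from an organ DCC table (pSv cm^2)."""
    weights = weights or icrp103_weights()
    rows = []
    for e in dose_df.columns:
        doses = dose_df[e].dropna().to_dict()
        uncs = (unc_df[e].dropna().to_dict() if unc_df is not None else None)
        ed, u = effective_dose(doses, weights, uncs, masses)
        rows.append((e, ed, u))
    return pd.DataFrame(rows, columns=["energy_MeV", "effective_dose", "uncertainty"]
                        ).set_index("energy_MeV")
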