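# voxdose

Voxel anthropomorphic phantom photon dosimetry: a self-contained toolkit
for building voxel body phantoms, transporting photons through them at
desk scale, projecting radiographs, computing ICRP-103 effective doses,
and reproducing the comparison statistics used in published dosimetric
model tables.

## Who it is for

Medical-physics researchers and students who want to exercise the full
voxel-phantom dosimetry chain — organ segmentation data model, Monte
Carlo input-deck preparation, fluence-to-dose conversion, effective-dose
weighting, model intercomparison — without a cluster, a cross-section
server, or access to a proprietary segmented CT volume.  A deterministic
synthetic 30-organ body stands in for real segmentation data; exports in
the four-card XML deck family (materials / geometry / settings /
tallies) let a prepared phantom be handed to a full-physics MC code.

## The model

A phantom is a lattice of cubic voxels labelled with organ IDs (air =
255), linearised x-fastest in plain-text *fill cards*.  An organ
registry maps each ID to a density and elemental mass fractions.
Photon interaction data come from a bundled per-element table of mass
attenuation and energy-absorption coefficients μ/ρ and μ_en/ρ
(cm²·g⁻¹), combined by Bragg additivity

    (μ/ρ)_tissue = Σ_e w_e (μ/ρ)_e ,

interpolated log–log in energy.  Two transport engines share this data:

* **Deterministic collision kerma** — one parallel ray per voxel column;
  per voxel the beam deposits `E · φ_in · (1 − e^(−μΔ)) · μ_en/μ`.
* **Analog Monte Carlo** — photoelectric absorption, Klein–Nishina
  Compton scattering (Kahn sampling), optional coherent channel; kerma
  approximation (energy transferred to electrons is deposited locally).

Organ absorbed doses follow the standard chain

    D_T = Heating_eV · C1 / Mass_T · C2        (pGy per particle)
    DCC_T = D_T / φ                            (pGy·cm²)
    ED = Σ_T w_T H_T + 0.12 · mean(H_rem)      (pSv·cm², photons: H_T = D_T)

with C1 = 1.602176634×10⁻¹⁹ J/eV, C2 = 10¹² pGy/Gy and the ICRP-103
tissue weighting factors (14 named organs, 13-tissue remainder).
Model comparison statistics (percent differences, pairwise-complete
RMSE, multi-model averages) operate on effective-dose series with
missing values.

## Worked example

```python
import numpy as np
from voxdose import synthetic, transport, dosimetry

body = synthetic.generate_body()            # 30 organs, (64,64,160) @ 0.4 cm
print(body.voxel_count, round(body.total_mass() / 1000, 1))
# 655360 15.7

dose_df, unc_df = dosimetry.compute_organ_dose_table(
    body, [0.05, 0.1, 0.5, 1.0], engine="kerma")
masses = {o.name: body.organ_mass(o.id) for o in body.registry}
ed = dosimetry.effective_dose_table(dose_df, unc_df, masses=masses)
print(ed["effective_dose"].round(4).to_dict())
# {0.05: 0.0977, 0.1: 0.1615, 0.5: 1.4969, 1.0: 3.2344}
```

The numbers are AP effective dose per unit fluence (pSv·cm²) for the
synthetic body; they rise monotonically with energy above 0.05 MeV, as
expected for a broad parallel beam (deeper penetration and larger kerma
per photon).

From the shell, the same workflows:

```sh
voxdose radiograph --energy 0.07,0.12        # contrast demo, PNG output
voxdose dose --energies default20 --engine kerma
voxdose compare                              # published-table statistics
voxdose export --out deck                    # four-card XML deck
```

`voxdose compare` recomputes, from the packaged published AP
effective-dose table, every pairwise RMSE — e.g. 0.157880 for OpenMC vs
the ICRP-116 reference and 0.225050 for MCNPX vs OpenMC over their 7
shared energies — using pairwise-complete-case statistics.

## Layout

- `voxdose.phantom` — organ registry, voxel lattice, fill-card I/O, slices
- `voxdose.materials` — element coefficient table, mixture rules
- `voxdose.synthetic` — deterministic stylized phantom generator
- `voxdose.transport` — ray traversal, radiography, kerma, analog MC
- `voxdose.dosimetry` — D_T, DCC, effective dose
- `voxdose.comparison` — percent differences, RMSE, model averages
- `voxdose.mc_export` — four-card XML deck writer/parser
- `voxdose.cli` — `voxdose` command-line entry points

See `docs/methods.md` for the physics assumptions, parameter defaults
and known limitations.
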