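"""Synthetic multi-omics metabolic-disease cohorts.

The generator emulates the design the analysis assumes: 49 serum samples in
seven disease groups of seven (healthy, obesity, MTS, hyperglycemia,
hypertension, hyperlipidemia, T2D), three omics layers with sparse zeros,
a clinical panel whose key factors honour the diagnostic criteria of each
disease label, and a latent three-group structure driving planted molecular
blocks:

* ``G1`` — favorable baseline;
* ``G2`` — dyslipidemia-like: a lipid-metabolite block and the lipid
  clinical axis (TG, LDL, ApoB, TCH, WaistCir) shifted up, an LCAT-like
  protein block shifted down;
* ``G3`` — glucose-dysregulated: FPG up, 0.5 h postprandial serum insulin
  down, an immune-peptide block (and, weakly, its source proteins) up.

Abundances are log-normal: group effects act additively on the log scale
(in units of the noise SD ``sigma``) through per-sample latent severity
factors that the relevant clinical factors also load on, so planted
molecules and their clinical axis are correlated by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DISEASES, ClinicalTable, CohortDesign, OmicsMatrix, PathwayDB, homa1

GROUPS = ("G1", "G2", "G3")

#: healthy-reference mean and SD per clinical factor (units in ClinicalTable).
FACTOR_BASELINES = {
    "BMI": (23.0, 2.5), "WaistCir": (80.0, 8.0),
    "FPG": (5.0, 0.5), "OGTT_2hPG": (6.0, 1.0),
    "SBP": (118.0, 8.0), "DBP": (76.0, 6.0),
    "TG": (1.1, 0.30), "HDL": (1.40, 0.25),
    "LDL": (2.5, 0.6), "ApoB": (0.9, 0.2), "TCH": (4.5, 0.8),
    "GPT": (22.0, 8.0), "GOT": (24.0, 7.0),
    "FPI": (8.0, 2.5), "PSI_0_5h": (60.0, 15.0),
}

#: additive shifts applied to each disease label's defining factors, sized
#: so the group means respect the diagnostic thresholds (waist >= 85/90 cm,
#: FPG >= 6.1 / 7 mmol/L, 2hPG >= 7.8 / 11.1, BP >= 130/85, TG > 1.7,
#: HDL < 1.04; MTS meets three or more criteria simultaneously).
DISEASE_SHIFTS = {
    "a": {},
    "b": {"BMI": 5.0, "WaistCir": 12.0},
    "c": {"BMI": 4.0, "WaistCir": 10.0, "FPG": 1.5, "OGTT_2hPG": 2.5,
          "SBP": 16.0, "DBP": 10.0, "TG": 1.0, "HDL": -0.40},
    "d": {"FPG": 1.2, "OGTT_2hPG": 2.2},
    "e": {"SBP": 18.0, "DBP": 12.0},
    "f": {"TG": 1.2, "HDL": -0.45},
    "g": {"FPG": 2.0, "OGTT_2hPG": 4.5},
}

#: clinical factor -> (latent axis, loading in factor-SD units).
CLINICAL_LOADINGS = {
    "TG": ("lip", 1.0), "LDL": ("lip", 0.8), "ApoB": ("lip", 0.8),
    "TCH": ("lip", 0.8), "WaistCir": ("lip", 0.6), "BMI": ("lip", 0.4),
    "HDL": ("lip", -0.5),
    "FPG": ("glc", 1.0), "OGTT_2hPG": ("glc", 0.8), "PSI_0_5h": ("glc", -0.9),
    "FPI": ("glc", 0.3),
    "SBP": ("bp", 0.8), "DBP": ("bp", 0.8),
}

#: disease -> probability of belonging to each latent group (G1, G2, G3);
#: MTS is entirely G2-like, T2D mostly G3-like, hypertension mostly
#: G1-like, mirroring the observed cluster-to-group flows.
DEFAULT_GROUP_MIXING = {
    "a": (1.00, 0.00, 0.00),
    "b": (0.60, 0.30, 0.10),
    "c": (0.00, 1.00, 0.00),
    "d": (0.40, 0.20, 0.40),
    "e": (0.80, 0.20, 0.00),
    "f": (0.30, 0.70, 0.00),
    "g": (0.10, 0.20, 0.70),
}


@dataclass
class SimulationConfig:
    """Tunable study design for the synthetic cohort.

    Effect sizes ``delta_lipid`` / ``delta_gluc`` are the latent-group mean
    shifts in units of the log-scale noise SD ``sigma``; molecules of a
    planted block load their latent axis with coefficient
    ``molecule_loading`` (also in SD units), so the realised log-abundance
    group shift of a planted molecule is ``delta * molecule_loading``.
    """

    n_per_disease: int = 7
    n_metabolites: int = 300
    n_proteins: int = 400
    n_peptides: int = 200
    sparsity: float = 0.2           # mean fraction of zero entries per layer
    sigma: float = 1.0              # log-scale noise SD
    delta_lipid: float = 3.0
    delta_gluc: float = 3.0
    latent_noise: float = 0.6       # within-group SD of the latent severity axes
    molecule_loading: float = 1.0
    clinical_latent_loading: float = 1.0
    clinical_noise: float = 0.5     # residual factor noise, in factor-SD units
    n_lipid_metabolites: int = 60
    n_lcat_proteins: int = 30
    n_immune_peptides: int = 48
    n_bp_proteins: int = 15
    group_mixing: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MIXING))
    expected_min_abs_rho: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.delta_lipid, self.delta_gluc) < 0 or self.sigma <= 0:
            raise ValueError("effect sizes must be >= 0 and sigma > 0")
        if not 0 <= self.sparsity <= 0.5:
            raise ValueError("sparsity must lie in [0, 0.5]")
        for d, probs in self.group_mixing.items():
            if d not in DISEASES or len(probs) != 3 or min(probs) < 0:
                raise ValueError(f"bad group mixing entry for {d!r}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"group mixing for {d!r} does not sum to 1")
        if self.expected_min_abs_rho > 0 and self.delta_lipid == 0 \
                and self.delta_gluc == 0:
            raise ValueError(
                "expected_min_abs_rho > 0 is unattainable with zero effect "
                "sizes; set expected_min_abs_rho=0 for null simulations")


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    for code in DISEASES:
        for i in range(config.n_per_disease):
            ids.append(f"{code}{i + 1:02d}")
            labels.append(code)
    return ids, labels


def _apply_sparsity(values: np.ndarray, config: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Left-censor entries below a per-molecule detection limit.

    Missing MS measurements concentrate at low abundance, so each row
    zeroes its lowest values; per-row censoring fractions are uniform on
    [0, 2*sparsity] (averaging ``sparsity``, a sparsity tail across
    molecules) and never exceed half the samples, so the sparsity filter
    keeps every simulated molecule.
    """
    n_mol, n_samp = values.shape
    cap = n_samp // 2
    rates = rng.uniform(0.0, 2.0 * config.sparsity, size=n_mol)
    n_zero = np.minimum(np.round(rates * n_samp).astype(int), cap)
    out = values.copy()
    order = np.argsort(values, axis=1)
    for i in range(n_mol):
        if n_zero[i]:
            out[i, order[i, :n_zero[i]]] = 0.0
    return out


def _layer_matrix(n_molecules: int, prefix: str, loadings: dict[int, tuple[str, float]],
                  latents: dict[str, np.ndarray], config: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    n_samples = len(next(iter(latents.values())))
    mu = rng.uniform(3.0, 8.0, size=n_molecules)
    log_x = mu[:, None] + config.sigma * rng.standard_normal((n_molecules, n_samples))
    for row, (axis, coef) in loadings.items():
        log_x[row] += coef * config.sigma * latents[axis]
    values = np.exp(log_x)
    values = _apply_sparsity(values, config, rng)
    ids = [f"{prefix}_{i + 1:04d}" for i in range(n_molecules)]
    return pd.DataFrame(values, index=ids)


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None):
    """Generate one synthetic cohort.

    Returns ``(matrices, clinical, design)`` where ``matrices`` maps layer
    name to :class:`OmicsMatrix`, and ``design`` records the true latent
    group of every sample and the planted molecule blocks.  Bit-reproducible
    for a fixed seed.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sample_ids, disease = _sample_ids(config)
    n = len(sample_ids)

    # latent group per sample, then latent severity axes
    probs = np.array([config.group_mixing[d] for d in disease])
    cum = probs.cumsum(axis=1)
    draws = rng.random(n)
    group_idx = (draws[:, None] >= cum).sum(axis=1)
    true_group = np.array(GROUPS)[group_idx]

    s = config.latent_noise
    latents = {
        "lip": config.delta_lipid * (true_group == "G2")
        + s * rng.standard_normal(n),
        "glc": config.delta_gluc * (true_group == "G3")
        + s * rng.standard_normal(n),
        "bp": rng.standard_normal(n),
    }

    b = config.molecule_loading
    lipid_rows = range(config.n_lipid_metabolites)
    met = _layer_matrix(config.n_metabolites, "MET",
                        {i: ("lip", b) for i in lipid_rows}, latents, config, rng)

    lcat_rows = range(config.n_lcat_proteins)
    immune_protein_rows = range(config.n_lcat_proteins,
                                config.n_lcat_proteins + config.n_immune_peptides // 2)
    bp_rows = range(immune_protein_rows.stop,
                    immune_protein_rows.stop + config.n_bp_proteins)
    prot_loadings: dict[int, tuple[str, float]] = {}
    prot_loadings.update({i: ("lip", -b) for i in lcat_rows})
    prot_loadings.update({i: ("glc", 0.4 * b) for i in immune_protein_rows})
    prot_loadings.update({i: ("bp", b) for i in bp_rows})
    prot = _layer_matrix(config.n_proteins, "PROT", prot_loadings,
                         latents, config, rng)

    pep_rows = range(config.n_immune_peptides)
    pep = _layer_matrix(config.n_peptides, "PEP",
                        {i: ("glc", b) for i in pep_rows}, latents, config, rng)

    # peptide -> source protein: immune peptides map onto the immune-protein
    # block (two peptides per protein); the rest map onto random proteins.
    annotations: dict[str, str] = {}
    immune_proteins = [prot.index[i] for i in immune_protein_rows]
    for j, row in enumerate(pep_rows):
        annotations[pep.index[row]] = immune_proteins[j % len(immune_proteins)]
    other_peps = [p for p in pep.index if p not in annotations]
    other_sources = rng.choice(
        prot.index[bp_rows.stop:], size=(len(other_peps) + 1) // 2, replace=False)
    for j, p in enumerate(other_peps):
        annotations[p] = str(other_sources[j % len(other_sources)])

    # clinical panel
    lam, eps = config.clinical_latent_loading, config.clinical_noise
    clinical = {}
    for factor, (mean, sd) in FACTOR_BASELINES.items():
        value = np.full(n, mean, dtype=float)
        value += np.array([DISEASE_SHIFTS[d].get(factor, 0.0) for d in disease])
        axis_coef = CLINICAL_LOADINGS.get(factor)
        if axis_coef is not None:
            axis, coef = axis_coef
            value += lam * coef * sd * latents[axis]
        value += eps * sd * rng.standard_normal(n)
        clinical[factor] = value
    clinical["FPG"] = np.maximum(clinical["FPG"], 3.8)
    for factor in ("TG", "HDL", "LDL", "ApoB", "TCH", "GPT", "GOT",
                   "FPI", "PSI_0_5h"):
        clinical[factor] = np.maximum(clinical[factor], 0.1)
    ir, beta = homa1(clinical["FPG"], clinical["FPI"])
    clinical["HOMA1_IR"] = ir
    clinical["HOMA1_B"] = beta
    clinical_df = pd.DataFrame(clinical, index=sample_ids)

    for df in (met, prot, pep):
        df.columns = sample_ids

    matrices = {
        "metabolite": OmicsMatrix("metabolite", met),
        "protein": OmicsMatrix("protein", prot),
        "peptide": OmicsMatrix("peptide", pep, annotations=annotations),
    }
    design = CohortDesign(
        disease=pd.Series(disease, index=sample_ids, name="disease"),
        true_group=pd.Series(true_group, index=sample_ids, name="true_group"),
        planted={
            "lipid_metabolites": [met.index[i] for i in lipid_rows],
            "lcat_proteins": [prot.index[i] for i in lcat_rows],
            "immune_proteins": immune_proteins,
            "bp_proteins": [prot.index[i] for i in bp_rows],
            "immune_peptides": [pep.index[i] for i in pep_rows],
        })
    return matrices, ClinicalTable(clinical_df), design


def generate_pathway_db(matrices: dict[str, OmicsMatrix], design: CohortDesign,
                        seed: int = 0, n_decoys_per_type: int = 10,
                        decoy_size: int = 30) -> PathwayDB:
    """Pathway sets over the simulated molecule universe.

    The planted blocks form two real pathways — ``lipid_metab`` (the lipid
    metabolite block plus the LCAT-like proteins) and ``complement_cascade``
    (the immune peptides' source proteins) — alongside random decoy sets of
    matched sizes drawn from the non-planted metabolite and protein
    universes (unrelated pathways do not contain the planted species).
    """
    rng = np.random.default_rng(seed)
    planted = design.planted
    planted_all = {m for block in planted.values() for m in block}
    metabolites = [m for m in matrices["metabolite"].molecule_ids
                   if m not in planted_all]
    proteins = [p for p in matrices["protein"].molecule_ids
                if p not in planted_all]
    pathways: dict[str, dict] = {
        "lipid_metab": {
            "name": "Lipid metabolism", "category": "metabolism",
            "members": planted["lipid_metabolites"] + planted["lcat_proteins"],
        },
        "complement_cascade": {
            "name": "Complement and coagulation cascades", "category": "immune",
            "members": planted["immune_proteins"],
        },
    }
    for t, universe in (("m", metabolites), ("p", proteins)):
        for i in range(n_decoys_per_type):
            members = rng.choice(universe, size=decoy_size, replace=False)
            pathways[f"decoy_{t}_{i + 1:02d}"] = {
                "name": f"Decoy {t.upper()} set {i + 1}",
                "category": "decoy", "members": [str(m) for m in members]}
    return PathwayDB(pathways)
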