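"""Synthetic combinatorial library and the two scoring oracles.

The generator enumerates an amide-coupled synthon space (A–B and A–B–C
couplings over three packaged fragment lists of 100 each, ~1.01 million
products) and exposes two deterministic scoring oracles standing in for the
expensive stages of a structure-based screen:

* **tier 1** — a fast docking-like score.  For molecule *m*,
  ``score = mu_1 + sigma_1 * (a·g(m) + b·h(m))`` with ``a = sqrt(signal_fraction)``
  and ``b = sqrt(1 − signal_fraction)``.  ``g`` is a fixed monotone
  (quantile-normalised) transform of a weighted descriptor sum, so its
  marginal over the library is standard normal; ``h`` is an independent
  hash-derived standard-normal deviate.  The score marginal is therefore
  Normal(mu_1, sigma_1²) by convolution, and the default calibration
  (mu_1 = −5.70, sigma_1 = 0.887) puts the 0.01% lower quantile at
  −9.0 kcal/mol.
* **tier 2** — a slower binding-energy-like score whose standardised latent
  is ``rho·z1 + sqrt(1 − rho²)·eps``, globally Pearson-correlated with
  tier 1 at ``rho`` (default 0.42).

Everything is a pure function of (config, seed): scores come from stable
64-bit hashes, never from global RNG state.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.special import ndtri

from . import chem_core
from .chem_core import MoleculeRecord, descriptor_vector
from .fragments import default_synthon_sets

logger = logging.getLogger(__name__)

LIBRARY_ID_PREFIX = "SYN"


class LibraryConfigError(ValueError):
    """Raised for invalid library configurations (e.g. a bad fragment)."""


@dataclass(frozen=True)
class LibraryConfig:
    """Configuration of the enumerable synthetic library.

    ``synthon_sets`` holds the (acyl, amino-core, amine) fragment lists in
    the SMILES prefix/infix/suffix convention of :mod:`alscreen.fragments`;
    ``coupling_rules`` selects which couplings are enumerated ("AB" joins an
    acyl with an amino core terminated as a free acid, "ABC" caps the core
    with an amine as a second amide).
    """

    n_molecules: int = 200_000
    seed: int = 0
    synthon_sets: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]] | None = None
    coupling_rules: tuple[str, ...] = ("AB", "ABC")

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise LibraryConfigError("n_molecules must be >= 1")
        if not self.coupling_rules or any(c not in ("AB", "ABC") for c in self.coupling_rules):
            raise LibraryConfigError("coupling_rules must be a subset of {'AB', 'ABC'}")

    def sets(self) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
        if self.synthon_sets is not None:
            a, b, c = self.synthon_sets
            if not (a and b and c):
                raise LibraryConfigError("synthon sets must be non-empty")
            return tuple(a), tuple(b), tuple(c)
        a, b, c = default_synthon_sets()
        return tuple(a), tuple(b), tuple(c)

    @property
    def space_size(self) -> int:
        a, b, c = self.sets()
        total = 0
        if "AB" in self.coupling_rules:
            total += len(a) * len(b)
        if "ABC" in self.coupling_rules:
            total += len(a) * len(b) * len(c)
        return total


def assemble_smiles(kind: str, a: str, b: str, c: str | None = None) -> str:
    """Assemble a product SMILES from fragment strings."""
    if kind == "AB":
        return a + b + "O"
    return a + b + c


def _index_parts(config: LibraryConfig, indices: np.ndarray):
    """Split mixed-radix enumeration indices into per-coupling (i, j, k)."""
    a, b, c = config.sets()
    na, nb, nc = len(a), len(b), len(c)
    n_ab = na * nb if "AB" in config.coupling_rules else 0
    out = []
    ab_mask = indices < n_ab
    if ab_mask.any():
        idx = indices[ab_mask]
        out.append(("AB", idx // nb, idx % nb, None, ab_mask))
    if (~ab_mask).any():
        idx = indices[~ab_mask] - n_ab
        out.append(("ABC", idx // (nb * nc), (idx // nc) % nb, idx % nc, ~ab_mask))
    return out


# --------------------------------------------------------------------------
# fragment-additive descriptor tables
# --------------------------------------------------------------------------

_table_cache: dict[tuple, dict] = {}


def _desc_or_raise(smiles: str, fragment: str) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LibraryConfigError(f"fragment {fragment!r} yields unparseable product {smiles!r}")
    return descriptor_vector(mol)


def _reference_tables(config: LibraryConfig) -> dict:
    """Per-fragment descriptor tables for additive reconstruction.

    RDKit's MW, Crippen logP, HBA/ring/rotatable counts and SMARTS counts are
    atom-additive with local typing, so over a fixed amide junction the
    descriptors of product (i, j, k) decompose exactly as
    D(i,0,0) + D(0,j,0) + D(0,0,k) − 2·D(0,0,0).  The decomposition is
    verified against direct computation on a sample at generation time and
    abandoned (per-molecule direct computation) if it does not hold for a
    custom fragment chemistry.
    """
    a, b, c = config.sets()
    key = (a, b, c, config.coupling_rules)
    cached = _table_cache.get(key)
    if cached is not None:
        return cached
    tables: dict = {}
    if "AB" in config.coupling_rules:
        e00 = _desc_or_raise(assemble_smiles("AB", a[0], b[0]), a[0])
        ei = np.stack([_desc_or_raise(assemble_smiles("AB", x, b[0]), x) for x in a])
        ej = np.stack([_desc_or_raise(assemble_smiles("AB", a[0], x), x) for x in b])
        tables["AB"] = (ei, ej, e00)
    if "ABC" in config.coupling_rules:
        d000 = _desc_or_raise(assemble_smiles("ABC", a[0], b[0], c[0]), a[0])
        di = np.stack([_desc_or_raise(assemble_smiles("ABC", x, b[0], c[0]), x) for x in a])
        dj = np.stack([_desc_or_raise(assemble_smiles("ABC", a[0], x, c[0]), x) for x in b])
        dk = np.stack([_desc_or_raise(assemble_smiles("ABC", a[0], b[0], x), x) for x in c])
        tables["ABC"] = (di, dj, dk, d000)
    _table_cache[key] = tables
    return tables


def _descriptors_for_indices(config: LibraryConfig, indices: np.ndarray) -> np.ndarray:
    tables = _reference_tables(config)
    out = np.empty((len(indices), len(chem_core.DESCRIPTOR_NAMES)))
    for kind, i, j, k, mask in _index_parts(config, indices):
        if kind == "AB":
            ei, ej, e00 = tables["AB"]
            out[mask] = ei[i] + ej[j] - e00
        else:
            di, dj, dk, d000 = tables["ABC"]
            out[mask] = di[i] + dj[j] + dk[k] - 2 * d000
    return out


def _smiles_for_indices(config: LibraryConfig, indices: np.ndarray) -> list[str]:
    a, b, c = config.sets()
    out: list[str] = [""] * len(indices)
    for kind, ii, jj, kk, mask in _index_parts(config, indices):
        positions = np.nonzero(mask)[0]
        if kind == "AB":
            for pos, i, j in zip(positions, ii, jj):
                out[pos] = a[i] + b[j] + "O"
        else:
            for pos, i, j, k in zip(positions, ii, jj, kk):
                out[pos] = a[i] + b[j] + c[k]
    return out


def _decomposition_valid(config: LibraryConfig, rng: np.random.Generator) -> bool:
    """Spot-check additive descriptors against direct RDKit computation."""
    total = config.space_size
    probe = np.unique(rng.integers(0, total, size=min(12, total)))
    approx = _descriptors_for_indices(config, probe)
    smiles = _smiles_for_indices(config, probe)
    for row, smi in zip(approx, smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise LibraryConfigError(f"enumerated product does not parse: {smi!r}")
        if not np.allclose(row, descriptor_vector(mol), atol=1e-6):
            return False
    return True


def generate_library(config: LibraryConfig) -> list[MoleculeRecord]:
    """Enumerate/subsample the synthon space into descriptor-bearing records.

    Products are enumerated in mixed-radix order (all A–B couplings first,
    then A–B–C); when ``n_molecules`` is below the space size a uniform
    subsample is drawn with the config seed.  Identifiers are stable
    zero-padded enumeration indices, so identical configs always reproduce
    identical records.
    """
    total = config.space_size
    if config.n_molecules > total:
        raise LibraryConfigError(
            f"n_molecules={config.n_molecules} exceeds enumerable space ({total})"
        )
    rng = np.random.default_rng(config.seed)
    if config.n_molecules == total:
        indices = np.arange(total)
    else:
        indices = np.sort(rng.choice(total, size=config.n_molecules, replace=False))
    if _decomposition_valid(config, rng):
        desc = _descriptors_for_indices(config, indices)
    else:  # custom chemistries fall back to direct per-molecule computation
        logger.warning("fragment-additive descriptors failed validation; computing directly")
        smiles = _smiles_for_indices(config, indices)
        desc = np.empty((len(indices), len(chem_core.DESCRIPTOR_NAMES)))
        for row, smi in enumerate(smiles):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise LibraryConfigError(f"enumerated product does not parse: {smi!r}")
            desc[row] = descriptor_vector(mol)
    smiles = _smiles_for_indices(config, indices)
    width = len(str(total - 1))
    records = [
        MoleculeRecord(
            id=f"{LIBRARY_ID_PREFIX}-{idx:0{width}d}",
            smiles=smi,
            mw=float(d[0]),
            clogp=float(d[1]),
            n_hba=int(round(d[2])),
            n_rings=int(round(d[3])),
            n_rotatable=int(round(d[4])),
            n_aromatic_rings=int(round(d[5])),
            n_acid=int(round(d[6])),
            formal_charge=int(round(d[7])),
        )
        for idx, smi, d in zip(indices, smiles, desc)
    ]
    return records


# --------------------------------------------------------------------------
# scoring oracles
# --------------------------------------------------------------------------

#: weights of the descriptor signal g over (mw, clogp, n_hba,
#: n_aromatic_rings, n_acid): acid groups and aromatic rings score
#: favourably (echoing the acid-rich, aromatic-flanked top scorers the
#: screen is meant to emulate), hydrophobicity is mildly penalised.
G_WEIGHTS = {"mw": -0.002, "clogp": 0.10, "n_hba": -0.10, "n_aromatic_rings": -0.30, "n_acid": -0.90}


@dataclass(frozen=True)
class OracleParams:
    """Parameters of the two synthetic scoring oracles.

    Defaults place the tier-1 Normal 1e−4 quantile at −9.0 kcal/mol
    (mu_1 − 3.719·sigma_1 = −9.0) and the tier-1/tier-2 correlation at 0.42.
    ``signal_fraction`` is the share of tier-1 score variance explained by
    descriptors (the learnable part); the remainder is molecule-specific
    hash noise.
    """

    mu_1: float = -5.70
    sigma_1: float = 0.887
    signal_fraction: float = 0.64
    rho: float = 0.42
    mu_2: float = -40.0
    sigma_2: float = 8.0
    seed: int = 0
    library_config: LibraryConfig = field(default_factory=LibraryConfig, compare=False)

    def __post_init__(self) -> None:
        if self.sigma_1 <= 0 or self.sigma_2 <= 0:
            raise ValueError("sigma_1 and sigma_2 must be positive")
        if not 0 <= self.signal_fraction <= 1:
            raise ValueError("signal_fraction must be in [0, 1]")
        if not -1 <= self.rho <= 1:
            raise ValueError("|rho| must be <= 1")


def _raw_signal(desc: np.ndarray) -> np.ndarray:
    names = chem_core.DESCRIPTOR_NAMES
    idx = {n: names.index(n) for n in G_WEIGHTS}
    return sum(w * desc[:, idx[n]] for n, w in G_WEIGHTS.items())


_calibration_cache: dict[tuple, np.ndarray] = {}


def _g_calibration(config: LibraryConfig) -> np.ndarray:
    """Sorted raw-signal values over the full enumerable space.

    Serves as the fixed reference distribution for the quantile→normal map
    of g; cached per synthon-set identity.
    """
    a, b, c = config.sets()
    key = (a, b, c, config.coupling_rules)
    cal = _calibration_cache.get(key)
    if cal is not None:
        return cal
    tables = _reference_tables(config)
    parts = []
    if "AB" in config.coupling_rules:
        ei, ej, e00 = tables["AB"]
        ri, rj = _raw_signal(ei), _raw_signal(ej)
        parts.append((ri[:, None] + rj[None, :] - _raw_signal(e00[None, :])[0]).ravel())
    if "ABC" in config.coupling_rules:
        di, dj, dk, d000 = tables["ABC"]
        ri, rj, rk = _raw_signal(di), _raw_signal(dj), _raw_signal(dk)
        r0 = _raw_signal(d000[None, :])[0]
        parts.append(
            (ri[:, None, None] + rj[None, :, None] + rk[None, None, :] - 2 * r0).ravel()
        )
    cal = np.sort(np.concatenate(parts))
    _calibration_cache[key] = cal
    return cal


def descriptor_signal(records: Sequence[MoleculeRecord], params: OracleParams) -> np.ndarray:
    """g(descriptors): quantile-normalised weighted descriptor sum, N(0,1) marginal."""
    desc = np.array(
        [[r.mw, r.clogp, r.n_hba, r.n_rings, r.n_rotatable, r.n_aromatic_rings, r.n_acid, r.formal_charge] for r in records]
    )
    raw = _raw_signal(desc)
    cal = _g_calibration(params.library_config)
    lo = np.searchsorted(cal, raw, side="left")
    hi = np.searchsorted(cal, raw, side="right")
    frac = (lo + hi) / 2 / len(cal)
    frac = np.clip(frac, 0.5 / len(cal), 1 - 0.5 / len(cal))
    return ndtri(frac)


def _hash_normal(ids: Sequence[str], seed: int, tag: str) -> np.ndarray:
    """Deterministic per-identifier standard-normal deviates.

    A stable 64-bit BLAKE2b hash of (id, seed, tag) is mapped to (0,1) and
    through the normal inverse CDF — reproducible across platforms, no
    global RNG state.
    """
    out = np.empty(len(ids))
    for n, mol_id in enumerate(ids):
        digest = hashlib.blake2b(f"{mol_id}|{seed}|{tag}".encode(), digest_size=8).digest()
        out[n] = int.from_bytes(digest, "big")
    return ndtri((out + 0.5) / 2.0**64)


def _tier1_latent(records: Sequence[MoleculeRecord], params: OracleParams) -> np.ndarray:
    a = math.sqrt(params.signal_fraction)
    b = math.sqrt(1 - params.signal_fraction)
    g = descriptor_signal(records, params) if a > 0 else 0.0
    h = _hash_normal([r.id for r in records], params.seed, "tier1")
    return a * g + b * h


def score_tier1_batch(records: Sequence[MoleculeRecord], params: OracleParams) -> np.ndarray:
    """Tier-1 (docking-like) scores in kcal/mol for a batch of records."""
    return params.mu_1 + params.sigma_1 * _tier1_latent(records, params)


def score_tier1(mol: MoleculeRecord, params: OracleParams) -> float:
    return float(score_tier1_batch([mol], params)[0])


def score_tier2_batch(records: Sequence[MoleculeRecord], params: OracleParams) -> np.ndarray:
    """Tier-2 (binding-energy-like) scores in kcal/mol for a batch of records."""
    z1 = _tier1_latent(records, params)
    eps = _hash_normal([r.id for r in records], params.seed, "tier2")
    z2 = params.rho * z1 + math.sqrt(1 - params.rho**2) * eps
    return params.mu_2 + params.sigma_2 * z2


def score_tier2(mol: MoleculeRecord, params: OracleParams) -> float:
    return float(score_tier2_batch([mol], params)[0])


# --------------------------------------------------------------------------
# pose fixtures
# --------------------------------------------------------------------------


def generate_poses(
    mols: Sequence[MoleculeRecord],
    seed: int,
    path: str,
    *,
    fixture_mode: bool = False,
    hotspot: tuple[float, float, float] = (0.0, 0.0, 0.0),
    feature: str = "carboxylic_acid",
) -> int:
    """Write one 3D conformer per molecule to an SDF (V2000) file.

    In ``fixture_mode`` each molecule's first matched feature atom (default:
    the carboxylate carbon) is translated to lie within 0.5 Å of ``hotspot``,
    giving density-grid analyses a known maximum.  Molecules that fail 3D
    embedding are skipped with a logged warning; the return value is the
    number of poses written.
    """
    if not mols:
        raise ValueError("generate_poses requires at least one molecule")
    rng = np.random.default_rng(seed)
    patt = chem_core.compiled_smarts(feature)
    writer = Chem.SDWriter(path)
    n_written = 0
    for rec in mols:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("skipping %s: unparseable SMILES", rec.id)
            continue
        molh = Chem.AddHs(mol)
        params3d = AllChem.ETKDGv3()
        embed_seed = int.from_bytes(
            hashlib.blake2b(f"{rec.id}|{seed}|pose".encode(), digest_size=4).digest(), "big"
        )
        params3d.randomSeed = embed_seed % (2**31 - 1)
        if AllChem.EmbedMolecule(molh, params3d) != 0:
            logger.warning("skipping %s: 3D embedding failed", rec.id)
            continue
        mol3d = Chem.RemoveHs(molh)
        if fixture_mode:
            matches = mol3d.GetSubstructMatches(patt)
            if matches:
                conf = mol3d.GetConformer()
                anchor = conf.GetAtomPosition(matches[0][0])
                jitter = rng.uniform(-0.25, 0.25, size=3)
                shift = np.asarray(hotspot) + jitter - np.array([anchor.x, anchor.y, anchor.z])
                for atom_idx in range(mol3d.GetNumAtoms()):
                    p = conf.GetAtomPosition(atom_idx)
                    conf.SetAtomPosition(atom_idx, (p.x + shift[0], p.y + shift[1], p.z + shift[2]))
        mol3d.SetProp("_Name", rec.id)
        writer.write(mol3d)
        n_written += 1
    writer.close()
    return n_written


# --------------------------------------------------------------------------
# assay fixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayTruth:
    """Ground-truth parameters behind the synthetic assay tables."""

    # calcein fluorescence time series (a.u. vs seconds)
    slopes: tuple[tuple[str, float], ...] = (("control", 100.0), ("compound", 50.0))
    background: float = 50.0
    n_timepoints: int = 30
    dt: float = 10.0
    # dose-response truth (three-parameter logistic, concentrations in µM)
    top: float = 1.0
    bottom: float = 0.0
    log_ic50: float = 0.5
    concentrations: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
    n_replicates: int = 3
    # ATPase truth: absorbance = intercept + slope·nmol Pi
    std_nmol: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 20.0, 40.0)
    std_slope: float = 0.02
    std_intercept: float = 0.05
    pi_nmol: tuple[tuple[str, float], ...] = (("verapamil", 24.0), ("compound", 12.0))
    vanadate_pi_nmol: float = 4.0
    reaction_time_min: float = 60.0
    protein_mg: float = 0.05


def three_param_logistic(x: np.ndarray, top: float, bottom: float, log_ic50: float) -> np.ndarray:
    """Y = Bottom + (Top − Bottom) / (1 + 10^(X − LogIC50)), X = log10 conc."""
    return bottom + (top - bottom) / (1 + 10.0 ** (np.asarray(x, dtype=float) - log_ic50))


def generate_assay_fixtures(
    true_params: AssayTruth, noise_sd: float, seed: int
) -> dict[str, pd.DataFrame]:
    """Synthesize the assay-analysis inputs with known ground truth.

    Returns four tables: ``fluorescence`` (time series per condition with the
    prescribed slopes plus Gaussian noise), ``dose_response`` (samples of the
    three-parameter logistic), ``atpase`` (absorbance per condition with and
    without vanadate) and ``atpase_standards`` (the phosphate standard curve).
    """
    if true_params.top <= true_params.bottom:
        raise ValueError("inhibition-curve truth requires Top > Bottom")
    if any(conc <= 0 for conc in true_params.concentrations):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)

    t = np.arange(true_params.n_timepoints) * true_params.dt
    rows = []
    for condition, slope in true_params.slopes:
        signal = true_params.background + slope * t + rng.normal(0, noise_sd, size=t.shape)
        for ti, si in zip(t, signal):
            rows.append({"time": ti, "signal": si, "background": true_params.background, "condition": condition})
    fluorescence = pd.DataFrame(rows)

    rows = []
    x = np.log10(np.array(true_params.concentrations))
    y_true = three_param_logistic(x, true_params.top, true_params.bottom, true_params.log_ic50)
    for rep in range(true_params.n_replicates):
        y = y_true + rng.normal(0, noise_sd, size=y_true.shape)
        for conc, yi in zip(true_params.concentrations, y):
            rows.append({"concentration_uM": conc, "response": yi, "replicate": rep})
    dose_response = pd.DataFrame(rows)

    std_abs = (
        true_params.std_intercept
        + true_params.std_slope * np.array(true_params.std_nmol)
        + rng.normal(0, noise_sd * true_params.std_slope, size=len(true_params.std_nmol))
    )
    atpase_standards = pd.DataFrame({"absorbance": std_abs, "nmol": true_params.std_nmol})

    rows = []
    for condition, nmol in true_params.pi_nmol:
        for vanadate in (False, True):
            pi = true_params.vanadate_pi_nmol if vanadate else nmol
            absorbance = (
                true_params.std_intercept
                + true_params.std_slope * pi
                + rng.normal(0, noise_sd * true_params.std_slope)
            )
            rows.append(
                {
                    "condition": condition,
                    "absorbance": absorbance,
                    "time_min": true_params.reaction_time_min,
                    "protein_mg": true_params.protein_mg,
                    "vanadate": vanadate,
                }
            )
    atpase = pd.DataFrame(rows)

    return {
        "fluorescence": fluorescence,
        "dose_response": dose_response,
        "atpase": atpase,
        "atpase_standards": atpase_standards,
    }
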