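"""Planted-motif simulator for protein-ligand interaction data.

The simulator builds a small world of random proteins and random ligand
token strings with known ground truth so the whole pipeline — encoding,
dataset unification, training and occlusion — can be exercised and scored
without any external downloads:

* proteins are i.i.d. uniform amino-acid strings with 1-3 known motifs
  planted at recorded, non-overlapping positions;
* "ligands" are vocabulary-valid SMILES token strings (not chemically
  valid molecules) that may carry designated pharmacophore tokens;
* binding affinity follows an interaction rule on the pK scale:
  ``base + bonus * (number of motif-pharmacophore matches) + N(0, sigma)``,
  so masking a matched motif genuinely destroys signal the model can use;
* dataset recipes emit regression sets with near-normal or skewed
  (floor-censored, emulating an assay-floor pile-up) affinity
  distributions, and classification sets binarized at a pK threshold with
  a configurable negative:positive ratio.

Defaults: base 4, bonus 1.5 and noise sigma 0.5 pK units, which under the
pK > 6 positivity threshold yield both classes with realistic overlap.
Everything is reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import STANDARD_AMINO_ACIDS, smiles_vocabulary
from .splitting import MANIFEST_COLUMNS, binarize_affinity, check_manifest

__all__ = [
    "WorldConfig",
    "DatasetRecipe",
    "SyntheticWorld",
    "DEFAULT_RECIPES",
    "simulate_world",
    "match_count",
    "assign_affinity",
    "emit_datasets",
]

# Planted motifs and their paired pharmacophore tokens.  Motifs are 8-mers
# over the amino-acid alphabet (a chance occurrence in a random background
# has probability 20^-8 per position); pairings are fixed: ligands carrying
# token i can bind the motif-i site.
DEFAULT_MOTIFS: tuple[str, ...] = ("WCWKCHND", "YFYHRMEY", "DGDESTAP")
DEFAULT_PHARMACOPHORES: tuple[str, ...] = ("N", "O", "S")

# Background ligand alphabet: vocabulary tokens that are not pharmacophores.
DEFAULT_LIGAND_ALPHABET: tuple[str, ...] = (
    "C", "c", "1", "2", "3", "(", ")", "=", "#", "F", "Cl", "Br", "[", "]", "+", "-",
)


@dataclass
class WorldConfig:
    """Generator state: everything needed to rebuild a world from the seed."""

    seed: int = 0
    n_proteins: int = 80
    n_ligands: int = 120
    protein_length: tuple[int, int] = (100, 160)   # residues, inclusive
    ligand_length: tuple[int, int] = (20, 50)      # tokens, inclusive
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    pharmacophores: tuple[str, ...] = DEFAULT_PHARMACOPHORES
    ligand_alphabet: tuple[str, ...] = DEFAULT_LIGAND_ALPHABET
    motifs_per_protein: tuple[int, int] = (1, 3)   # inclusive range
    pharmacophore_prob: float = 2.0 / 3.0          # per ligand, per token
    base_affinity: float = 4.0                     # pK units
    match_bonus: float = 1.5                       # pK units per match
    noise_sd: float = 0.5                          # pK units
    censor_floor: float = 5.0                      # pK floor for skewed recipes

    def __post_init__(self) -> None:
        if len(self.motifs) != len(self.pharmacophores):
            raise ValueError("need one pharmacophore token per motif")
        if any(set(m) - set(STANDARD_AMINO_ACIDS) for m in self.motifs):
            raise ValueError("motifs must use standard amino acids")
        vocab = smiles_vocabulary()
        for tok in tuple(self.pharmacophores) + tuple(self.ligand_alphabet):
            if tok not in vocab:
                raise ValueError(f"ligand token {tok!r} not in the SMILES vocabulary")
        if set(self.pharmacophores) & set(self.ligand_alphabet):
            raise ValueError("pharmacophore tokens must not appear in the background alphabet")
        lo, hi = self.motifs_per_protein
        if not (1 <= lo <= hi <= len(self.motifs)):
            raise ValueError("motifs_per_protein range must fit the motif library")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DatasetRecipe:
    """One emitted dataset: task type, size, shape and class balance."""

    name: str
    task: str                       # classification | regression
    n_pairs: int
    shape: str = "normal"           # normal | skewed (floor-censored)
    neg_pos_ratio: float = 1.0      # classification only
    threshold: float = 6.0          # pK positivity threshold

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.shape not in ("normal", "skewed"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


DEFAULT_RECIPES: tuple[DatasetRecipe, ...] = (
    DatasetRecipe("reg_normal", "regression", 2500, shape="normal"),
    DatasetRecipe("reg_skewed", "regression", 1500, shape="skewed"),
    DatasetRecipe("cls_balanced", "classification", 3000, neg_pos_ratio=1.0),
    DatasetRecipe("cls_imbalanced", "classification", 2000, neg_pos_ratio=3.0),
)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    proteins: dict                  # protein_id -> sequence
    motif_sites: dict               # protein_id -> [(start, end, motif_index)], 0-based half-open
    ligands: dict                   # ligand_id -> token string
    ligand_pharmacophores: dict     # ligand_id -> set of motif indices matched

    def protein_ids(self) -> list[str]:
        return list(self.proteins)

    def ligand_ids(self) -> list[str]:
        return list(self.ligands)

    def truth_intervals(self, protein_id: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, _ in self.motif_sites[protein_id]]

    def matched_intervals(self, protein_id: str, ligand_id: str) -> list[tuple[int, int]]:
        """Intervals of the motifs this ligand can actually engage."""
        pharms = self.ligand_pharmacophores[ligand_id]
        return [(s, e) for s, e, m in self.motif_sites[protein_id] if m in pharms]


def _plant_motifs(seq: list[str], motifs: list[tuple[int, str]],
                  rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Place motifs at uniform non-overlapping positions (rejection sampling)."""
    sites: list[tuple[int, int, int]] = []
    for midx, motif in motifs:
        w = len(motif)
        for _ in range(1000):
            start = int(rng.integers(0, len(seq) - w + 1))
            if all(start + w <= s or start >= e for s, e, _ in sites):
                break
        else:
            raise RuntimeError("could not place motifs without overlap; protein too short")
        seq[start : start + w] = list(motif)
        sites.append((start, start + w, midx))
    return sorted(sites)


def simulate_world(config: WorldConfig | None = None) -> SyntheticWorld:
    """Draw a reproducible world of proteins and ligands from the seed."""
    if config is None:
        config = WorldConfig()
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(STANDARD_AMINO_ACIDS))
    proteins: dict = {}
    motif_sites: dict = {}
    for i in range(config.n_proteins):
        pid = f"P{i:04d}"
        length = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
        seq = list(rng.choice(aa, size=length))
        k = int(rng.integers(config.motifs_per_protein[0], config.motifs_per_protein[1] + 1))
        chosen = rng.choice(len(config.motifs), size=k, replace=False)
        motifs = [(int(m), config.motifs[int(m)]) for m in chosen]
        motif_sites[pid] = _plant_motifs(seq, motifs, rng)
        proteins[pid] = "".join(seq)

    alphabet = np.array(config.ligand_alphabet, dtype=object)
    ligands: dict = {}
    ligand_pharms: dict = {}
    for i in range(config.n_ligands):
        lid = f"L{i:04d}"
        length = int(rng.integers(config.ligand_length[0], config.ligand_length[1] + 1))
        tokens = list(rng.choice(alphabet, size=length))
        matched = set()
        for midx, tok in enumerate(config.pharmacophores):
            if rng.random() < config.pharmacophore_prob:
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens.insert(pos, tok)
                matched.add(midx)
        ligands[lid] = "".join(tokens)
        ligand_pharms[lid] = matched
    return SyntheticWorld(config=config, proteins=proteins, motif_sites=motif_sites,
                          ligands=ligands, ligand_pharmacophores=ligand_pharms)


def match_count(world: SyntheticWorld, protein_id: str, ligand_id: str) -> int:
    """Number of motif-pharmacophore matches for a pair."""
    planted = {m for _, _, m in world.motif_sites[protein_id]}
    return len(planted & world.ligand_pharmacophores[ligand_id])


def assign_affinity(
    protein_id: str,
    ligand_id: str,
    world: SyntheticWorld,
    rng: np.random.Generator | None = None,
    censor: bool = False,
) -> float:
    """pK affinity: base + bonus per match + Gaussian noise.

    ``censor`` applies the skewed-recipe floor: values below
    ``censor_floor`` are clamped to it, producing the pile-up typical of
    assay-floor kinase data.
    """
    cfg = world.config
    value = cfg.base_affinity + cfg.match_bonus * match_count(world, protein_id, ligand_id)
    if cfg.noise_sd > 0 and rng is not None:
        value += rng.normal(0.0, cfg.noise_sd)
    if censor:
        value = max(value, cfg.censor_floor)
    return float(value)


def _sample_pairs(world: SyntheticWorld, n: int, rng: np.random.Generator,
                  exclude: set) -> list[tuple[str, str]]:
    pids, lids = world.protein_ids(), world.ligand_ids()
    total = len(pids) * len(lids)
    pairs: list[tuple[str, str]] = []
    seen = set(exclude)
    attempts = 0
    while len(pairs) < n and attempts < 50 * n and len(seen) < total:
        pid = pids[int(rng.integers(len(pids)))]
        lid = lids[int(rng.integers(len(lids)))]
        attempts += 1
        if (pid, lid) in seen:
            continue
        seen.add((pid, lid))
        pairs.append((pid, lid))
    return pairs


def emit_datasets(
    world: SyntheticWorld,
    recipes: tuple[DatasetRecipe, ...] = DEFAULT_RECIPES,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Build the interaction manifest for the recipes (optionally write files).

    Regression recipes keep real pK values (floor-censored for the skewed
    shape).  Classification recipes binarize affinity at the recipe
    threshold and fill positive/negative quotas at the recipe
    negative:positive ratio by stratified pair sampling, so the emitted
    ratio is exact up to rounding.  Pairs are unique within a dataset.

    When ``out_dir`` is given, writes ``proteins.fasta``, ``ligands.tsv``,
    ``manifest.tsv`` and ``truth_sites.bed`` (0-based half-open).
    """
    rng = np.random.default_rng(np.random.SeedSequence([world.config.seed, 1]))
    records = []
    for recipe in recipes:
        used: set = set()
        if recipe.task == "regression":
            pairs = _sample_pairs(world, recipe.n_pairs, rng, used)
            for pid, lid in pairs:
                value = assign_affinity(pid, lid, world, rng,
                                        censor=recipe.shape == "skewed")
                records.append((pid, lid, recipe.name, "regression", value))
        else:
            n_pos = int(round(recipe.n_pairs / (1.0 + recipe.neg_pos_ratio)))
            n_neg = recipe.n_pairs - n_pos
            quota = {1: n_pos, 0: n_neg}
            got = {1: 0, 0: 0}
            attempts = 0
            while (got[1] < quota[1] or got[0] < quota[0]) and attempts < 200 * recipe.n_pairs:
                attempts += 1
                cand = _sample_pairs(world, 1, rng, used)
                if not cand:
                    break
                pid, lid = cand[0]
                used.add((pid, lid))
                value = assign_affinity(pid, lid, world, rng,
                                        censor=recipe.shape == "skewed")
                label = int(binarize_affinity([value], recipe.threshold)[0])
                if got[label] < quota[label]:
                    got[label] += 1
                    records.append((pid, lid, recipe.name, "classification", label))
            if got[1] < quota[1] or got[0] < quota[0]:
                warnings.warn(
                    f"recipe {recipe.name!r}: filled {got[1]}/{quota[1]} positives and "
                    f"{got[0]}/{quota[0]} negatives before exhausting candidate pairs")
    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    check_manifest(manifest)
    if out_dir is not None:
        from . import io as plio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        plio.write_fasta(out / "proteins.fasta", world.proteins)
        plio.write_ligand_table(out / "ligands.tsv", world.ligands)
        plio.write_manifest(out / "manifest.tsv", manifest)
        truth = {pid: [(s, e, world.config.motifs[m]) for s, e, m in sites]
                 for pid, sites in world.motif_sites.items()}
        plio.write_bed(out / "truth_sites.bed", truth)
    return manifest
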