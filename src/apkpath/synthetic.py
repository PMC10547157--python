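"""Synthetic inputs with declared statistical structure.

Everything the pipeline consumes can be generated here: initial-rate
Michaelis-Menten assays (0-110 mM grids in triplicate), cascade time
courses sampled every 2 h, and toy aligned protein families for the
consensus-selection stage.  Each generator is deterministic under its
seed, records the generating truth in metadata so recovery can be
scored, and reports (never hides) any clipping of negative noise draws.

The default error model is multiplicative Gaussian with a 5% coefficient
of variation: assay scatter scales with signal, and the triplicate error
bars this emulates are reported only as a standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fitting import InitialRateAssay, michaelis_menten
from .kinetics import KineticParameterSet, TimecourseDataset, simulate
from .network import PathwayDesign
from .species import SpeciesRegistry

#: 12 concentrations spanning the assayed 0-110 mM range
DEFAULT_ASSAY_GRID = np.array(
    [1.0, 2.0, 5.0, 7.5, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 85.0, 110.0]
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

NOISE_KINDS = ("multiplicative_gaussian", "additive_gaussian", "none")


@dataclass(frozen=True)
class NoiseModel:
    """Seeded noise specification for rates or concentrations."""

    kind: str = "multiplicative_gaussian"
    cv: float = 0.05
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.sd < 0:
            raise ValueError("cv and sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(
        self, values: np.ndarray, rng: Optional[np.random.Generator] = None
    ) -> tuple[np.ndarray, int]:
        """Perturbed copy plus the count of negative draws clipped to 0."""
        values = np.asarray(values, dtype=float)
        if self.kind == "none":
            return values.copy(), 0
        rng = rng or self.rng()
        z = rng.standard_normal(values.shape)
        if self.kind == "multiplicative_gaussian":
            noisy = values * (1.0 + self.cv * z)
        else:
            noisy = values + self.sd * z
        n_clipped = int(np.sum(noisy < 0))
        return np.clip(noisy, 0.0, None), n_clipped


NO_NOISE = NoiseModel(kind="none")


def gen_mm_assay(
    true_kcat: float,
    true_km: float,
    *,
    substrate: str = "DHA",
    grid: Optional[Sequence[float]] = None,
    replicates: int = 3,
    noise: NoiseModel = NO_NOISE,
    enzyme_loading: float = 0.25,
    molar_mass: float = 92.0,
) -> InitialRateAssay:
    """Synthetic initial-rate assay around a Michaelis-Menten truth.

    Rates are in mM/min for an enzyme at ``enzyme_loading`` mg/mL with
    the given molar mass (defaults follow the 0.25 mg/mL kinetics
    assays).  Metadata records the generating truth and clip count.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = DEFAULT_ASSAY_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D concentration list")
    vmax = true_kcat * (enzyme_loading / molar_mass) * 60.0  # mM/min
    truth = michaelis_menten(grid, vmax, true_km)
    clean = np.tile(truth, (replicates, 1))
    noisy, n_clipped = noise.apply(clean)
    return InitialRateAssay(
        substrate=substrate,
        concentrations=grid,
        rates=noisy,
        enzyme_loading=enzyme_loading,
        molar_mass=molar_mass,
        metadata={
            "true_kcat": true_kcat,
            "true_km": true_km,
            "true_vmax": vmax,
            "noise": noise,
            "n_clipped": n_clipped,
        },
    )


def gen_timecourse(
    design: PathwayDesign,
    params: KineticParameterSet,
    y0: Mapping[str, float],
    noise: NoiseModel = NO_NOISE,
    registry: Optional[SpeciesRegistry] = None,
    **simulate_kwargs,
) -> TimecourseDataset:
    """Simulated cascade time course perturbed by the noise model.

    With ``noise=NO_NOISE`` the output equals ``simulate()`` exactly.
    Negative draws are clipped at zero and the count recorded in
    metadata, never silently.
    """
    clean = simulate(design, params, y0, registry=registry, **simulate_kwargs)
    noisy, n_clipped = noise.apply(clean.conc)
    metadata = dict(clean.metadata)
    metadata.update({"noise": noise, "n_clipped": n_clipped})
    return TimecourseDataset(
        time=clean.time, species=clean.species, conc=noisy, metadata=metadata
    )


@dataclass(frozen=True)
class ProteinFamily:
    """A gap-free aligned family derived from a recorded ancestor."""

    ancestor: str
    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    mutation_rate: float
    seed: int

    def alignment(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.sequences))

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, path, "fasta")


def gen_protein_family(
    length: int,
    n_sequences: int,
    mutation_rate: float,
    seed: int = 0,
    alphabet: str = AMINO_ACIDS,
) -> ProteinFamily:
    """Family of sequences mutated independently per position from an ancestor.

    Each position of each sequence mutates with probability
    ``mutation_rate`` to a uniformly chosen *different* residue, so the
    family's column consensus estimates the ancestor.
    """
    if length < 1 or n_sequences < 1:
        raise ValueError("length and n_sequences must be >= 1")
    if not (0.0 <= mutation_rate < 1.0):
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    k = len(letters)
    ancestor_idx = rng.integers(0, k, size=length)
    seqs = []
    for _ in range(n_sequences):
        idx = ancestor_idx.copy()
        mask = rng.random(length) < mutation_rate
        if mask.any():
            # shift by 1..k-1 guarantees a different residue
            shift = rng.integers(1, k, size=int(mask.sum()))
            idx[mask] = (idx[mask] + shift) % k
        seqs.append("".join(letters[idx]))
    ancestor = "".join(letters[ancestor_idx])
    ids = tuple(f"seq{i:03d}" for i in range(n_sequences))
    return ProteinFamily(
        ancestor=ancestor,
        ids=ids,
        sequences=tuple(seqs),
        mutation_rate=mutation_rate,
        seed=seed,
    )
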