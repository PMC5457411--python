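"""Synthetic UMI-bottleneck PCR-fidelity experiments with full ground truth.

This module emulates the five-stage assay used to measure polymerase
fidelity: (1) each template molecule is tagged with a random unique
molecular identifier (UMI) during a single linear-amplification synthesis,
(2) the tagged molecules are amplified by PCR modeled as a Galton-Watson
branching process (each molecule spawns one copy per cycle with probability
``efficiency - 1``, and every newly synthesized strand may acquire
substitution errors), (3) a dilution bottleneck retains at most one
first-PCR molecule per UMI, (4) a second PCR multiplies the surviving
molecule into a read family, and (5) sequencing emits Phred-scored reads
carrying the UMI as a prefix.

Because every simulated error is recorded in a :class:`TruthRecord`, every
downstream stage (UMI grouping, consensus assembly, error calling, rate
estimation, spectrum recovery) can be audited against ground truth.

The non-bottlenecked protocol variant omits the dilution step, so reads of
one UMI descend from many independent first-PCR lineages and only the
linear-amplification errors survive consensus assembly; this is the
configuration used to measure the linear-amplification error rate itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "SUBSTITUTIONS",
    "DEFAULT_TEMPLATE",
    "PolymeraseModel",
    "ExperimentConfig",
    "TruthRecord",
    "SimRead",
    "SequencingResult",
    "SimulatedRun",
    "amplification_fold",
    "simulate_linear_amplification",
    "simulate_pcr_population",
    "sample_lineage",
    "simulate_first_pcr",
    "simulate_dilution",
    "bottleneck_survivors",
    "simulate_sequencing",
    "simulate_unamplified_control",
    "run_experiment",
]

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LOOKUP = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LOOKUP[_b] = _i

#: The twelve strand-aware substitution classes, in canonical order.
SUBSTITUTIONS = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

#: Default 150-nt template; fixed so that simulated experiments are
#: reproducible and the base composition (A48/C38/G25/T39) is uneven enough
#: to exercise composition normalization.
DEFAULT_TEMPLATE = (
    "AGCGTACAAACGAATCATCAATTGATCCAACGTCGTGTCCTGTAGGAGGGAACTAATGACCCATGAATAA"
    "AAATTGAACTCTGTTATCAAACGATCTCCCTCTAACCGCGCTTGCTATCTAGTGCTCATGACGATAATAC"
    "ATCCTTCACA"
)


class ConfigError(ValueError):
    """Raised when a configuration or model parameter is out of range."""


def _as_spectrum(spectrum) -> np.ndarray:
    """Coerce a 12-weight substitution spectrum to a normalized array."""
    if isinstance(spectrum, Mapping):
        arr = np.array([float(spectrum.get(s, 0.0)) for s in SUBSTITUTIONS])
    else:
        arr = np.asarray(spectrum, dtype=float)
    if arr.shape != (12,):
        raise ConfigError(f"spectrum must have 12 weights, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ConfigError("spectrum weights must be nonnegative")
    total = arr.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ConfigError(f"spectrum weights must sum to 1 (got {total!r})")
    return arr / total


@dataclass(frozen=True)
class PolymeraseModel:
    """Error model of one polymerase.

    Parameters
    ----------
    name
        Assay label.
    per_synthesis_error_rate
        Probability of a substitution per template base per synthesis
        event (one strand copied once); must lie in [0, 0.01].
    spectrum
        Twelve nonnegative weights over :data:`SUBSTITUTIONS` summing to 1.
        The weights are the *composition-normalized* substitution shares:
        the share recovered by the spectrum estimator after dividing class
        counts by the template fraction of the source base.
    efficiency
        Expected fold-amplification per PCR cycle, in [1, 2]; a molecule is
        copied once per cycle with probability ``efficiency - 1``.
    """

    name: str
    per_synthesis_error_rate: float
    spectrum: np.ndarray
    efficiency: float = 1.8

    def __post_init__(self):
        object.__setattr__(self, "spectrum", _as_spectrum(self.spectrum))
        if not (0.0 <= self.per_synthesis_error_rate <= 0.01):
            raise ConfigError(
                f"per_synthesis_error_rate must be in [0, 0.01], "
                f"got {self.per_synthesis_error_rate}"
            )
        if not (1.0 <= self.efficiency <= 2.0):
            raise ConfigError(f"efficiency must be in [1, 2], got {self.efficiency}")

    def with_rate(self, rate: float) -> "PolymeraseModel":
        return replace(self, per_synthesis_error_rate=rate)


#: Uniform spectrum, handy as a neutral default.
UNIFORM_SPECTRUM = np.full(12, 1.0 / 12.0)


@dataclass
class ExperimentConfig:
    """Parameters of one simulated assay (field names mirror the config file)."""

    template: str = DEFAULT_TEMPLATE
    umi_length: int = 14
    la_error_rate: float = 1e-4
    pcr1_cycles: int = 20
    dilution_fraction: float = 1e-6
    pcr2_cycles: int = 25
    reads_per_umi_distribution: dict = field(
        default_factory=lambda: {"kind": "negative_binomial", "mean": 10.0, "shape": 10.0}
    )
    read_length: int | None = None
    phred_quality: float = 30.0
    phred_sd: float = 0.0
    bottlenecked: bool = True
    seed: int = 0
    n_templates: int = 10000

    def __post_init__(self):
        self.template = str(self.template).upper()
        if not self.template or set(self.template) - set(BASES):
            raise ConfigError("template: must be a nonempty ACGT string")
        if self.umi_length < 1:
            raise ConfigError("umi_length: must be >= 1")
        if self.pcr1_cycles < 1:
            raise ConfigError("pcr1_cycles: must be >= 1")
        if not (0.0 < self.dilution_fraction <= 1.0):
            raise ConfigError("dilution_fraction: must be in (0, 1]")
        if self.pcr2_cycles < 0:
            raise ConfigError("pcr2_cycles: must be >= 0")
        if not (0.0 <= self.la_error_rate <= 1.0):
            raise ConfigError("la_error_rate: must be in [0, 1]")
        if self.n_templates < 0:
            raise ConfigError("n_templates: must be >= 0")
        mean = float(self.reads_per_umi_distribution.get("mean", 0)) if isinstance(
            self.reads_per_umi_distribution, Mapping
        ) else 0
        kind = (self.reads_per_umi_distribution or {}).get("kind", "")
        if kind == "constant":
            mean = float(self.reads_per_umi_distribution.get("value", 0))
        if mean < 1:
            raise ConfigError("reads_per_umi_distribution: mean must be >= 1")

    @property
    def effective_read_length(self) -> int:
        return self.read_length or (self.umi_length + len(self.template))


@dataclass
class TruthRecord:
    """Ground truth for one UMI-tagged molecule.

    ``molecule_sequence`` differs from the template exactly at the union of
    the recorded error positions (1-based); ``lineage_depth`` counts the
    synthesis events along the sampled first-PCR lineage.
    """

    umi: str
    molecule_sequence: str
    la_errors: list = field(default_factory=list)
    pcr1_errors: list = field(default_factory=list)
    lineage_depth: int = 0

    def error_positions(self) -> set:
        return {p for p, _, _ in self.la_errors} | {p for p, _, _ in self.pcr1_errors}


class SimRead(NamedTuple):
    name: str
    sequence: str
    quality: str
    molecule_index: int


class SequencingResult(NamedTuple):
    reads: list
    read_counts: np.ndarray


@dataclass
class SimulatedRun:
    """Everything a simulated experiment produced, with ground truth."""

    config: ExperimentConfig
    polymerase: PolymeraseModel
    molecules: list          # all UMI-tagged molecules after linear amplification
    sequenced: list          # molecules that entered sequencing (post-bottleneck)
    final_population_sizes: np.ndarray | None
    reads: list
    read_counts: np.ndarray


# --------------------------------------------------------------------------
# Elementary operations


def amplification_fold(efficiency: float, cycles: int) -> float:
    """Expected fold-amplification after ``cycles`` PCR cycles.

    With efficiency 1.8 and 20 cycles this is ~1.27e5, i.e. ~1.3 x 10^5.
    """
    if not (1.0 <= efficiency <= 2.0):
        raise ConfigError(f"efficiency must be in [1, 2], got {efficiency}")
    if cycles < 0:
        raise ConfigError(f"cycles must be >= 0, got {cycles}")
    return float(efficiency) ** cycles


class _SubstitutionSampler:
    """Draws substitution events for a fixed (template, spectrum) pair.

    Each event picks its class with probability proportional to the
    spectrum weight times the template fraction of the class's source base,
    then a uniformly random template position carrying that base.  Class
    counts are therefore proportional to ``f_src * w``, and the
    composition-normalized spectrum statistic (class count divided by
    source-base fraction, renormalized) is an unbiased estimator of the
    generator weights ``w``.
    """

    def __init__(self, template: str, spectrum: np.ndarray):
        codes = np.frombuffer(template.encode(), dtype=np.uint8)
        self.positions = {b: np.flatnonzero(codes == ord(b)) for b in BASES}
        # class probability = spectrum weight x source-base template
        # fraction, so class counts come out proportional to f_src * w and
        # the composition-normalized estimator (count / f_src) recovers w
        L = len(template)
        w = np.array(spectrum, dtype=float)
        for i, sub in enumerate(SUBSTITUTIONS):
            w[i] *= self.positions[sub[0]].size / L
        if w.sum() <= 0:
            raise ConfigError("template carries no base targeted by the spectrum")
        self.cumulative = np.cumsum(w / w.sum())

    def draw(self, k: int, rng: np.random.Generator, taken: set | None = None) -> list:
        """Draw ``k`` events as (1-based position, ref, alt) tuples.

        Positions listed in ``taken`` (0-based) are excluded and newly
        drawn positions are added to it, so a lineage mutates any given
        position at most once.
        """
        if taken is None:
            taken = set()
        events = []
        for _ in range(k):
            cls = int(np.searchsorted(self.cumulative, rng.random(), side="right"))
            cls = min(cls, 11)
            src, alt = SUBSTITUTIONS[cls][0], SUBSTITUTIONS[cls][2]
            candidates = self.positions[src]
            pos = None
            for _attempt in range(64):
                trial = int(candidates[rng.integers(candidates.size)])
                if trial not in taken:
                    pos = trial
                    break
            if pos is None:
                free = [int(p) for p in candidates if int(p) not in taken]
                if not free:
                    continue  # every source-base position already mutated
                pos = free[int(rng.integers(len(free)))]
            taken.add(pos)
            events.append((pos + 1, src, alt))
        return events


def _apply_errors(template: str, errors: Iterable) -> str:
    seq = bytearray(template.encode())
    for pos, _ref, alt in errors:
        seq[pos - 1] = ord(alt)
    return seq.decode()


def _random_umis(n: int, length: int, rng: np.random.Generator) -> list:
    codes = _BASE_CODES[rng.integers(0, 4, size=(n, length))]
    return [codes[i].tobytes().decode() for i in range(n)]


def simulate_linear_amplification(
    config: ExperimentConfig,
    polymerase: PolymeraseModel,
    n_templates: int,
    rng: np.random.Generator,
) -> list:
    """Tag ``n_templates`` molecules with fresh UMIs in one synthesis event.

    Each product is a first-generation copy of the template: errors are
    injected once at ``config.la_error_rate`` (expected ``L * rate`` errors
    per molecule), with substitution classes drawn from the polymerase
    spectrum.
    """
    if n_templates < 1:
        raise ConfigError("n_templates must be >= 1")
    L = len(config.template)
    umis = _random_umis(n_templates, config.umi_length, rng)
    molecules = [TruthRecord(umi=u, molecule_sequence=config.template) for u in umis]
    if config.la_error_rate > 0:
        sampler = _SubstitutionSampler(config.template, polymerase.spectrum)
        n_errors = rng.binomial(L, config.la_error_rate, size=n_templates)
        for i in np.flatnonzero(n_errors):
            events = sampler.draw(int(n_errors[i]), rng)
            if events:
                molecules[i].la_errors = events
                molecules[i].molecule_sequence = _apply_errors(config.template, events)
    return molecules


def simulate_pcr_population(
    molecule: TruthRecord,
    polymerase: PolymeraseModel,
    cycles: int,
    rng: np.random.Generator,
    max_population: int = 200_000,
) -> list:
    """Explicit Galton-Watson amplification of one molecule.

    Every cycle each molecule spawns one copy with probability
    ``efficiency - 1``; each new copy acquires fresh synthesis errors.
    Only feasible for small cycle counts; for large amplifications use
    :func:`sample_lineage`, which draws one final molecule with the same
    distribution without building the tree.
    """
    if cycles < 0:
        raise ConfigError("cycles must be >= 0")
    expected = amplification_fold(polymerase.efficiency, cycles)
    if expected > max_population:
        raise ConfigError(
            f"expected population {expected:.3g} exceeds {max_population}; "
            "use sample_lineage for large amplifications"
        )
    template = molecule.molecule_sequence
    L = len(template)
    sampler = _SubstitutionSampler(template, polymerase.spectrum)
    rate = polymerase.per_synthesis_error_rate
    birth_p = polymerase.efficiency - 1.0
    population = [replace(molecule, la_errors=list(molecule.la_errors),
                          pcr1_errors=list(molecule.pcr1_errors))]
    for _cycle in range(cycles):
        n = len(population)
        copied = np.flatnonzero(rng.random(n) < birth_p)
        n_errors = rng.binomial(L, rate, size=copied.size) if rate > 0 else np.zeros(copied.size, int)
        for j, parent_idx in enumerate(copied):
            parent = population[parent_idx]
            child = TruthRecord(
                umi=parent.umi,
                molecule_sequence=parent.molecule_sequence,
                la_errors=list(parent.la_errors),
                pcr1_errors=list(parent.pcr1_errors),
                lineage_depth=parent.lineage_depth + 1,
            )
            if n_errors[j] > 0:
                taken = {p - 1 for p in child.error_positions()}
                events = sampler.draw(int(n_errors[j]), rng, taken=taken)
                if events:
                    child.pcr1_errors.extend(events)
                    child.molecule_sequence = _apply_errors(
                        template, child.la_errors + child.pcr1_errors
                    )
            population.append(child)
    return population


def _lineage_depths(
    n: int, cycles: int, birth_p: float, rng: np.random.Generator
) -> tuple:
    """Depths of uniformly sampled final molecules from ``n`` branching trees.

    Simulates each tree's population-size trajectory ``N_t`` forward, then
    walks one uniformly chosen final molecule backward: at cycle ``t`` the
    sampled molecule is one of the ``B_t`` new copies with probability
    ``B_t / N_t`` (one synthesis event), else it is a survivor.  Returns
    ``(depths, final_sizes)``.
    """
    N = np.ones(n, dtype=np.int64)
    depths = np.zeros(n, dtype=np.int64)
    if birth_p > 0:
        for _t in range(cycles):
            B = rng.binomial(N, birth_p)
            N = N + B
            depths += rng.random(n) < (B / N)
    return depths, N


def sample_lineage(
    molecule: TruthRecord,
    polymerase: PolymeraseModel,
    cycles: int,
    rng: np.random.Generator,
) -> TruthRecord:
    """One molecule distributed as a uniform draw from the full PCR population.

    Errors are injected once per synthesis event along the sampled lineage
    (``lineage_depth`` events in total, each an independent per-base
    Bernoulli trial at the per-synthesis rate).
    """
    if cycles < 0:
        raise ConfigError("cycles must be >= 0")
    depth_arr, _N = _lineage_depths(1, cycles, polymerase.efficiency - 1.0, rng)
    depth = int(depth_arr[0])
    template = molecule.molecule_sequence
    out = TruthRecord(
        umi=molecule.umi,
        molecule_sequence=template,
        la_errors=list(molecule.la_errors),
        pcr1_errors=list(molecule.pcr1_errors),
        lineage_depth=molecule.lineage_depth + depth,
    )
    rate = polymerase.per_synthesis_error_rate
    if depth > 0 and rate > 0:
        k = int(rng.binomial(len(template) * depth, rate))
        if k:
            sampler = _SubstitutionSampler(template, polymerase.spectrum)
            taken = {p - 1 for p in out.error_positions()}
            events = sampler.draw(k, rng, taken=taken)
            out.pcr1_errors.extend(events)
            out.molecule_sequence = _apply_errors(template, out.la_errors + out.pcr1_errors)
    return out


def simulate_first_pcr(
    molecules: Sequence[TruthRecord],
    polymerase: PolymeraseModel,
    cycles: int,
    rng: np.random.Generator,
    template: str | None = None,
) -> tuple:
    """Vectorized lineage sampling for a whole cohort of tagged molecules.

    Equivalent to calling :func:`sample_lineage` per molecule; returns
    ``(sampled_molecules, final_population_sizes)`` where the sizes feed the
    dilution-bottleneck survival probabilities.  Substitution classes and
    positions are drawn against the reference ``template`` (default: the
    first molecule's pre-error template is unknown here, so pass the
    experiment template when molecules already carry LA errors).
    """
    n = len(molecules)
    if n == 0:
        return [], np.zeros(0, dtype=np.int64)
    ref = template if template is not None else molecules[0].molecule_sequence
    L = len(ref)
    depths, sizes = _lineage_depths(n, cycles, polymerase.efficiency - 1.0, rng)
    rate = polymerase.per_synthesis_error_rate
    n_errors = rng.binomial(depths * L, rate) if rate > 0 else np.zeros(n, dtype=np.int64)
    sampler = _SubstitutionSampler(ref, polymerase.spectrum) if rate > 0 else None
    out = []
    for i, mol in enumerate(molecules):
        rec = TruthRecord(
            umi=mol.umi,
            molecule_sequence=mol.molecule_sequence,
            la_errors=list(mol.la_errors),
            pcr1_errors=list(mol.pcr1_errors),
            lineage_depth=mol.lineage_depth + int(depths[i]),
        )
        if n_errors[i] > 0:
            taken = {p - 1 for p in rec.error_positions()}
            events = sampler.draw(int(n_errors[i]), rng, taken=taken)
            if events:
                rec.pcr1_errors.extend(events)
                rec.molecule_sequence = _apply_errors(ref, rec.la_errors + rec.pcr1_errors)
        out.append(rec)
    return out, sizes


def simulate_dilution(
    population: Mapping[str, Sequence[TruthRecord]],
    dilution_fraction: float,
    rng: np.random.Generator,
) -> dict:
    """Bottleneck an explicit population: at most one molecule per UMI survives.

    Each molecule is sampled independently with probability
    ``dilution_fraction``; if several molecules of one UMI are drawn, one of
    them is kept uniformly at random.
    """
    if not (0.0 < dilution_fraction <= 1.0):
        raise ConfigError("dilution_fraction must be in (0, 1]")
    survivors = {}
    for umi in population:
        members = population[umi]
        if not len(members):
            continue
        drawn = np.flatnonzero(rng.random(len(members)) < dilution_fraction)
        if drawn.size:
            survivors[umi] = members[int(drawn[int(rng.integers(drawn.size))])]
    return survivors


def bottleneck_survivors(
    molecules: Sequence[TruthRecord],
    final_sizes: np.ndarray,
    dilution_fraction: float,
    rng: np.random.Generator,
) -> list:
    """Dilution bottleneck for lineage-sampled cohorts.

    A UMI whose first PCR produced ``N`` molecules survives with probability
    ``1 - (1 - f)^N``; the surviving molecule is the already-sampled uniform
    lineage draw.  UMI collisions are capped at one molecule per tag.
    """
    if not (0.0 < dilution_fraction <= 1.0):
        raise ConfigError("dilution_fraction must be in (0, 1]")
    sizes = np.asarray(final_sizes, dtype=float)
    p_survive = -np.expm1(sizes * np.log1p(-dilution_fraction))
    keep = rng.random(len(molecules)) < p_survive
    seen = set()
    out = []
    for i in np.flatnonzero(keep):
        mol = molecules[int(i)]
        if mol.umi in seen:
            continue
        seen.add(mol.umi)
        out.append(mol)
    return out


# --------------------------------------------------------------------------
# Sequencing


def _draw_read_counts(descriptor: Mapping, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = descriptor.get("kind", "negative_binomial")
    if kind == "constant":
        return np.full(n, int(descriptor["value"]), dtype=np.int64)
    if kind == "poisson":
        return rng.poisson(float(descriptor["mean"]), size=n).astype(np.int64)
    if kind == "negative_binomial":
        mean = float(descriptor["mean"])
        shape = float(descriptor.get("shape", 10.0))
        p = shape / (shape + mean)
        return rng.negative_binomial(shape, p, size=n).astype(np.int64)
    raise ConfigError(f"reads_per_umi_distribution: unknown kind {kind!r}")


def _shared_trajectory_depths(
    n_mol: int,
    counts: np.ndarray,
    cycles: int,
    birth_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-read lineage depths sharing each molecule's size trajectory.

    Each molecule gets one forward population-size trajectory; each of its
    reads walks an independent lineage backward through that trajectory.
    Shared ancestry between reads of one molecule (common subtrees) is not
    modeled.
    """
    total = int(counts.sum())
    if cycles == 0 or birth_p <= 0 or total == 0:
        return np.zeros(total, dtype=np.int64)
    N = np.ones(n_mol, dtype=np.int64)
    ratios = np.empty((n_mol, cycles), dtype=float)
    for t in range(cycles):
        B = rng.binomial(N, birth_p)
        N = N + B
        ratios[:, t] = B / N
    per_read = np.repeat(ratios, counts, axis=0)
    return (rng.random(per_read.shape) < per_read).sum(axis=1).astype(np.int64)


def _inject_read_errors(
    reads_mat: np.ndarray,
    depths: np.ndarray,
    polymerase: PolymeraseModel,
    template: str,
    umi_length: int,
    rng: np.random.Generator,
) -> None:
    """In-place per-read substitution errors (independent across reads)."""
    rate = polymerase.per_synthesis_error_rate
    if rate <= 0:
        return
    L = len(template)
    read_len = reads_mat.shape[1]
    k = rng.binomial(depths * L, rate)
    hit = np.flatnonzero(k)
    if hit.size == 0:
        return
    sampler = _SubstitutionSampler(template, polymerase.spectrum)
    for i in hit:
        for pos, _ref, alt in sampler.draw(int(k[i]), rng):
            col = umi_length + pos - 1
            if col < read_len:
                reads_mat[i, col] = ord(alt)


def simulate_sequencing(
    molecules: Sequence[TruthRecord],
    config: ExperimentConfig,
    rng: np.random.Generator,
    *,
    pcr2_polymerase: PolymeraseModel | None = None,
    first_pcr_polymerase: PolymeraseModel | None = None,
    fastq_path=None,
) -> SequencingResult:
    """Emit Phred-scored reads (UMI prefix + insert) for the given molecules.

    In the bottlenecked protocol every read copies its molecule's sequence;
    in the non-bottlenecked protocol (``first_pcr_polymerase`` given) each
    read additionally carries the errors of an independently sampled
    first-PCR lineage, so first-PCR errors do not reach consensus majority.
    ``pcr2_polymerase`` adds independent per-read second-PCR lineage errors.
    Sequencing noise flips each base with probability ``10**(-Q/10)`` to a
    uniformly chosen other base; the written quality string reflects the
    per-base scores used.
    """
    n_mol = len(molecules)
    L = len(config.template)
    umi_len = config.umi_length
    read_len = config.effective_read_length
    counts = _draw_read_counts(config.reads_per_umi_distribution, n_mol, rng) \
        if n_mol else np.zeros(0, dtype=np.int64)
    total = int(counts.sum())

    if total == 0:
        if fastq_path is not None:
            open(fastq_path, "w").close()
        return SequencingResult([], counts)

    full = np.empty((n_mol, umi_len + L), dtype=np.uint8)
    for i, mol in enumerate(molecules):
        full[i, :umi_len] = np.frombuffer(mol.umi.encode(), dtype=np.uint8)
        full[i, umi_len:] = np.frombuffer(mol.molecule_sequence.encode(), dtype=np.uint8)
    reads_mat = np.repeat(full[:, :read_len], counts, axis=0).copy()
    mol_idx = np.repeat(np.arange(n_mol), counts)

    if first_pcr_polymerase is not None and config.pcr1_cycles > 0:
        d1 = _shared_trajectory_depths(
            n_mol, counts, config.pcr1_cycles,
            first_pcr_polymerase.efficiency - 1.0, rng,
        )
        _inject_read_errors(reads_mat, d1, first_pcr_polymerase,
                            config.template, umi_len, rng)
    if pcr2_polymerase is not None and config.pcr2_cycles > 0:
        d2 = _shared_trajectory_depths(
            n_mol, counts, config.pcr2_cycles,
            pcr2_polymerase.efficiency - 1.0, rng,
        )
        _inject_read_errors(reads_mat, d2, pcr2_polymerase,
                            config.template, umi_len, rng)

    # sequencing noise
    if math.isinf(config.phred_quality):
        qual_mat = np.full(reads_mat.shape, 41, dtype=np.int64)
    else:
        if config.phred_sd > 0:
            qual_mat = np.clip(
                np.rint(rng.normal(config.phred_quality, config.phred_sd,
                                   size=reads_mat.shape)), 2, 41
            ).astype(np.int64)
        else:
            qual_mat = np.full(reads_mat.shape,
                               int(round(config.phred_quality)), dtype=np.int64)
        p_err = 10.0 ** (-qual_mat / 10.0)
        flips = rng.random(reads_mat.shape) < p_err
        n_flips = int(flips.sum())
        if n_flips:
            old = _CODE_LOOKUP[reads_mat[flips]]
            reads_mat[flips] = _BASE_CODES[(old + rng.integers(1, 4, size=n_flips)) % 4]
    qual_bytes = (qual_mat + 33).astype(np.uint8)

    reads = [
        SimRead(
            name=f"sim_{i}",
            sequence=reads_mat[i].tobytes().decode(),
            quality=qual_bytes[i].tobytes().decode(),
            molecule_index=int(mol_idx[i]),
        )
        for i in range(total)
    ]
    if fastq_path is not None:
        from . import io as _io
        _io.write_fastq(fastq_path, reads)
    return SequencingResult(reads, counts)


def simulate_unamplified_control(
    template: str,
    n_reads: int,
    rng: np.random.Generator,
    *,
    bridge_polymerase: PolymeraseModel | None = None,
    bridge_error_rate: float = 0.0,
    quality_mean: float = 35.0,
    quality_sd: float = 3.0,
) -> list:
    """Reads of an unamplified library: bridge-PCR errors plus sequencing noise.

    Bridge (cluster-generation) errors are quality-independent — they are
    real base calls of an erroneous cluster consensus — while sequencing
    noise is tied to the per-base Phred score.  Raising a quality threshold
    therefore enriches for the bridge-error signature.
    """
    L = len(template)
    mat = np.tile(np.frombuffer(template.encode(), dtype=np.uint8), (n_reads, 1))
    if bridge_polymerase is not None and bridge_error_rate > 0:
        sampler = _SubstitutionSampler(template, bridge_polymerase.spectrum)
        k = rng.binomial(L, bridge_error_rate, size=n_reads)
        for i in np.flatnonzero(k):
            for pos, _ref, alt in sampler.draw(int(k[i]), rng):
                mat[i, pos - 1] = ord(alt)
    qual = np.clip(
        np.rint(rng.normal(quality_mean, quality_sd, size=mat.shape)), 2, 41
    ).astype(np.int64)
    flips = rng.random(mat.shape) < 10.0 ** (-qual / 10.0)
    n_flips = int(flips.sum())
    if n_flips:
        old = _CODE_LOOKUP[mat[flips]]
        mat[flips] = _BASE_CODES[(old + rng.integers(1, 4, size=n_flips)) % 4]
    qual_bytes = (qual + 33).astype(np.uint8)
    return [
        SimRead(f"ctrl_{i}", mat[i].tobytes().decode(),
                qual_bytes[i].tobytes().decode(), i)
        for i in range(n_reads)
    ]


def run_experiment(
    config: ExperimentConfig,
    polymerase: PolymeraseModel,
    *,
    pcr2_polymerase: PolymeraseModel | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedRun:
    """Full protocol: tagging, first PCR, bottleneck (optional), sequencing.

    Bottlenecked runs measure first-PCR plus linear-amplification errors;
    non-bottlenecked runs measure linear-amplification errors only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    molecules = simulate_linear_amplification(config, polymerase, config.n_templates, rng)
    if config.bottlenecked:
        amplified, sizes = simulate_first_pcr(
            molecules, polymerase, config.pcr1_cycles, rng, template=config.template
        )
        sequenced = bottleneck_survivors(amplified, sizes, config.dilution_fraction, rng)
        result = simulate_sequencing(
            sequenced, config, rng, pcr2_polymerase=pcr2_polymerase
        )
        return SimulatedRun(config, polymerase, amplified, sequenced, sizes,
                            result.reads, result.read_counts)
    sequenced = molecules
    result = simulate_sequencing(
        sequenced, config, rng,
        first_pcr_polymerase=polymerase, pcr2_polymerase=pcr2_polymerase,
    )
    return SimulatedRun(config, polymerase, molecules, sequenced, None,
                        result.reads, result.read_counts)
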