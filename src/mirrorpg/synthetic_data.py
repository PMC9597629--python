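"""Synthetic proteogenomic test-bed with planted reannotation events.

Generates a toy bacterial genome with annotated CDSs, a configurable number
of deliberately mis-annotated start codons (annotation shifted downstream)
and hidden ORFs (real CDSs omitted from the annotation), then simulates the
full experimental design: parallel trypsin and lysargiNase digests, paired
14N/15N spectra of every detected peptide, and a dimethyl-labelled
N-terminome subset.  A ground-truth manifest makes end-to-end recovery
checkable.

Design notes
------------
* Intergenic sequence is stop-enriched (an all-frame stop cassette every
  ~45 nt) so each gene occupies its own stop-to-stop ORF and hidden ORFs
  are unambiguous.
* Mis-annotated genes carry a K/R at residue 2 and no in-frame start codon
  inside the extension window, so the planted event is detectable by fully
  specific peptides and its true start is the unique upstream candidate.
  Without such a site an extension would be invisible to any specific
  search and the simulation would test nothing.
* The aminopeptidase initiator-removal rule is shared verbatim with
  start-codon inference (`constants.INITIATOR_REMOVAL_RESIDUES`).
* Precursor charge is fixed at 2, inside the accepted 2-6 range, keeping
  the spectrum model minimal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np

from .constants import (
    CODON_TABLE,
    GENERATOR_START_CODONS,
    INITIATOR_REMOVAL_RESIDUES,
    START_CODONS,
    STOP_CODONS,
    translate_codon,
)
from .digestion import LYSARGINASE, TRYPSIN, cleavage_boundaries, digest
from .mass_model import (
    CARBAMIDOMETHYL_C,
    DIMETHYL_K,
    DIMETHYL_N_TERM,
    apply_fixed_mods,
    fragment_ions,
    precursor_mz,
)
from .reannotation import AnnotationRecord, PipelineConfig, write_annotation_gff3
from .sixframe_db import Genome, write_genome_fasta
from .spectra_scoring import Spectrum, write_mgf

#: Stops in all three frames on both strands regardless of phase.
_STOP_CASSETTE = "TTATTATTATAATAATAA"

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
del _AA_TO_CODONS["*"]

_AA20 = sorted(_AA_TO_CODONS)

RUN_NAMES = (
    "trypsin_14N",
    "trypsin_15N",
    "lysarginase_14N",
    "lysarginase_15N",
    "nterm",
)


class GenerationError(ValueError):
    """Configuration infeasible for the requested genome."""


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulation."""

    seed: int = 17
    genome_length: int = 60_000
    n_genes: int = 60
    n_mis_start: int = 4
    mis_start_shift: tuple[int, int] = (3, 10)  # codons, inclusive range
    n_hidden_orfs: int = 3
    gene_length_codons: tuple[int, int] = (60, 180)
    peptide_detection_prob: float = 0.9
    fragment_dropout_prob: float = 0.15
    noise_peaks_per_spectrum: int = 10
    intensity_sigma: float = 0.5  # log-normal mu=0
    n15_fraction: float = 1.0
    nterm_evidence_fraction: float = 0.5
    max_missed: int = 2
    min_len: int = 7
    max_len: int = 45

    def __post_init__(self) -> None:
        for name in (
            "peptide_detection_prob", "fragment_dropout_prob",
            "n15_fraction", "nterm_evidence_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_mis_start > self.n_genes:
            raise ValueError("more mis-annotated starts than genes")


@dataclass
class GeneTruth:
    """True and annotated coordinates of one planted gene."""

    gene_id: str
    strand: str
    true_cds: tuple[int, int]  # 1-based inclusive, stop codon included
    annotated_cds: tuple[int, int] | None  # None for hidden ORFs
    start_codon: str
    mis_start: bool
    hidden: bool
    initiator_removed: bool
    protein: str  # full translation, initiator included
    mature_protein: str

    @property
    def mature_offset(self) -> int:
        """0 when the initiator is retained, 1 when removed."""
        return len(self.protein) - len(self.mature_protein)


@dataclass
class SpectrumTruth:
    """The generating peptide of one simulated spectrum."""

    title: str
    gene_id: str
    peptide: str
    start: int  # 1-based in the mature protein
    end: int
    protease: str
    isotope: str


@dataclass
class GroundTruth:
    """Manifest tying the emitted files back to the planted truth."""

    genome_id: str
    seed: int
    genes: list[GeneTruth] = field(default_factory=list)
    spectra: dict[str, list[SpectrumTruth]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "genome_id": self.genome_id,
            "seed": self.seed,
            "genes": [asdict(g) for g in self.genes],
            "spectra": {
                run: [asdict(s) for s in entries]
                for run, entries in self.spectra.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        truth = cls(genome_id=data["genome_id"], seed=data["seed"])
        for g in data["genes"]:
            g["true_cds"] = tuple(g["true_cds"])
            if g["annotated_cds"] is not None:
                g["annotated_cds"] = tuple(g["annotated_cds"])
            truth.genes.append(GeneTruth(**g))
        truth.spectra = {
            run: [SpectrumTruth(**s) for s in entries]
            for run, entries in data["spectra"].items()
        }
        return truth


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def _stop_rich_spacer(rng: np.random.Generator, length: int) -> str:
    """Intergenic filler with an all-frame stop cassette every ~45 nt."""
    parts: list[str] = []
    n = 0
    while n < length:
        take = min(len(_STOP_CASSETTE), length - n)
        parts.append(_STOP_CASSETTE[:take])
        n += take
        k = min(27, length - n)
        if k:
            parts.append(_random_dna(rng, k))
            n += k
    return "".join(parts)


def _pick_codon(
    rng: np.random.Generator, aa: str, forbid_starts: bool = False
) -> str:
    options = _AA_TO_CODONS[aa]
    if forbid_starts:
        options = [c for c in options if c not in START_CODONS]
        if not options:
            raise GenerationError(f"no non-start codon for {aa}")
    return options[rng.integers(len(options))]


def _gene_codons(
    rng: np.random.Generator,
    n_codons: int,
    guard_until: int = 0,
    kr_positions: tuple[int, ...] = (),
) -> list[str]:
    """Coding codons (start codon first, stop excluded).

    Codon positions 2..guard_until avoid start-codon strings (and M, whose
    only codon is ATG); positions in ``kr_positions`` carry K or R (K/R
    codons are never start codons) so that planted events have fully
    specific peptides of observable length around the start region.
    """
    codons = [GENERATOR_START_CODONS[rng.integers(len(GENERATOR_START_CODONS))]]
    for pos in range(2, n_codons + 1):
        if pos in kr_positions:
            aa = "KR"[rng.integers(2)]
            codons.append(_pick_codon(rng, aa))
            continue
        guard = pos <= guard_until
        aa = _AA20[rng.integers(len(_AA20))]
        while guard and aa == "M":
            aa = _AA20[rng.integers(len(_AA20))]
        codons.append(_pick_codon(rng, aa, forbid_starts=guard))
    return codons


def _mature(protein: str) -> tuple[str, bool]:
    if len(protein) > 1 and protein[1] in INITIATOR_REMOVAL_RESIDUES:
        return protein[1:], True
    return protein, False


def generate_truth_set(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[Genome, list[AnnotationRecord], GroundTruth]:
    """Build the genome, the (partly wrong) annotation and the truth manifest.

    Deterministic for a given config and generator state.  Hidden ORFs are
    present in the genome but absent from the annotation; mis-annotated
    genes have their GFF start shifted downstream by 3-10 codons.
    """
    n_units = config.n_genes + config.n_hidden_orfs
    hidden_idx = set(
        rng.choice(n_units, size=config.n_hidden_orfs, replace=False).tolist()
    )
    gene_positions = [i for i in range(n_units) if i not in hidden_idx]
    mis_idx = set(
        np.asarray(gene_positions)[
            rng.choice(len(gene_positions), size=config.n_mis_start, replace=False)
        ].tolist()
    )

    stops = sorted(STOP_CODONS)
    cassettes: list[tuple[str, dict]] = []
    lo, hi = config.gene_length_codons
    shift_lo, shift_hi = config.mis_start_shift
    n_gene = n_hidden = 0
    for i in range(n_units):
        hidden = i in hidden_idx
        mis = i in mis_idx
        n_codons = int(rng.integers(lo, hi + 1))
        shift = int(rng.integers(shift_lo, shift_hi + 1)) if mis else 0
        if mis:
            # a K/R right after the start plus one at observable distance
            # keep the planted extension detectable by fully specific
            # peptides within the searched length window
            anchor = int(rng.integers(max(10, shift + 4), 41))
            kr_positions = (2, anchor)
        else:
            kr_positions = ()
        codons = _gene_codons(
            rng,
            n_codons,
            guard_until=shift + 3 if mis else 0,
            kr_positions=kr_positions,
        )
        strand = "+-"[rng.integers(2)]
        stop = stops[rng.integers(len(stops))]
        cds_nt = "".join(codons) + stop
        if hidden:
            gene_id = f"hidden_{n_hidden:02d}"
            n_hidden += 1
        else:
            gene_id = f"gene_{n_gene:03d}"
            n_gene += 1
        cassettes.append(
            (
                cds_nt,
                {
                    "gene_id": gene_id,
                    "strand": strand,
                    "hidden": hidden,
                    "mis": mis,
                    "shift": shift,
                    "codons": codons,
                },
            )
        )

    total_coding = sum(len(nt) + 3 for nt, _ in cassettes)  # +3 upstream stop
    n_gaps = n_units + 1
    remaining = config.genome_length - total_coding
    if remaining < 60 * n_gaps:
        raise GenerationError(
            f"genome_length {config.genome_length} too small for "
            f"{n_units} genes ({total_coding} coding nt)"
        )
    gap = remaining // n_gaps
    gap_last = remaining - gap * (n_gaps - 1)

    pieces: list[str] = []
    cursor = 0
    genes: list[GeneTruth] = []
    annotation: list[AnnotationRecord] = []
    for i, (cds_nt, meta) in enumerate(cassettes):
        spacer = _stop_rich_spacer(rng, gap)
        pieces.append(spacer)
        cursor += len(spacer)
        if meta["strand"] == "+":
            block = "TAA" + cds_nt  # in-frame stop bounding the ORF upstream
            true_cds = (cursor + 4, cursor + 3 + len(cds_nt))
        else:
            from .constants import reverse_complement

            block = reverse_complement(cds_nt) + "TTA"
            true_cds = (cursor + 1, cursor + len(cds_nt))
        pieces.append(block)
        cursor += len(block)

        protein = "".join(translate_codon(c) for c in meta["codons"])
        mature, removed = _mature(protein)
        shift_nt = 3 * meta["shift"]
        if meta["hidden"]:
            annotated = None
        elif meta["strand"] == "+":
            annotated = (true_cds[0] + shift_nt, true_cds[1])
        else:
            annotated = (true_cds[0], true_cds[1] - shift_nt)
        genes.append(
            GeneTruth(
                gene_id=meta["gene_id"],
                strand=meta["strand"],
                true_cds=true_cds,
                annotated_cds=annotated,
                start_codon=meta["codons"][0],
                mis_start=meta["mis"],
                hidden=meta["hidden"],
                initiator_removed=removed,
                protein=protein,
                mature_protein=mature,
            )
        )
        if annotated is not None:
            annotation.append(
                AnnotationRecord(
                    gene_id=meta["gene_id"],
                    strand=meta["strand"],
                    cds_start=annotated[0],
                    cds_end=annotated[1],
                    product=f"synthetic protein {meta['gene_id']}",
                )
            )
    pieces.append(_stop_rich_spacer(rng, gap_last))
    genome = Genome(id="synthetic_chromosome", sequence="".join(pieces))
    truth = GroundTruth(genome_id=genome.id, seed=config.seed, genes=genes)
    return genome, annotation, truth


# ---------------------------------------------------------------------------
# Spectrum simulation


def _spectrum_from_fragments(
    title: str,
    mz_values: np.ndarray,
    intensities: np.ndarray,
    precursor: float,
    rng: np.random.Generator,
    config: SyntheticConfig,
    label: str,
) -> Spectrum:
    noise_mz = rng.uniform(150.0, 1600.0, config.noise_peaks_per_spectrum)
    noise_int = rng.uniform(0.01, 0.1, config.noise_peaks_per_spectrum)
    return Spectrum(
        spectrum_id=title,
        precursor_mz=precursor,
        precursor_charge=2,
        mz=np.concatenate([mz_values, noise_mz]),
        intensity=np.concatenate([intensities, noise_int]),
        label=label,
    )


def _nterm_peptide(gene: GeneTruth, config: SyntheticConfig) -> tuple[str, int] | None:
    """The dimethyl N-terminal (semi-tryptic) peptide of a mature protein.

    Runs from residue 1 to the nearest tryptic boundary giving a peptide
    within the length window and the semi-specific missed-cleavage budget.
    Returns (sequence, end) or None when no boundary qualifies.
    """
    bounds = cleavage_boundaries(gene.mature_protein, TRYPSIN)
    for k, b in enumerate(bounds[1:], start=1):
        if b < config.min_len or k - 1 > 3:
            continue
        if b > config.max_len:
            return None
        return gene.mature_protein[:b], b
    return None


def simulate_spectra(
    truth: GroundTruth, config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, list[Spectrum]]:
    """Simulate the five MGF runs from the true proteome.

    Every detected peptide (Bernoulli ``peptide_detection_prob``) yields a
    14N spectrum of its singly-charged b/y ions minus Bernoulli dropouts,
    with log-normal intensities and uniform noise peaks; with probability
    ``n15_fraction`` a 15N twin with the same dropout pattern and the same
    intensities is emitted (modelling near-identical metabolic-label
    pairs).  Planted events additionally receive a dimethyl N-terminome
    spectrum with probability ``nterm_evidence_fraction``.
    """
    runs: dict[str, list[Spectrum]] = {name: [] for name in RUN_NAMES}
    truth.spectra = {name: [] for name in RUN_NAMES}
    counter = {name: 0 for name in RUN_NAMES}

    def emit(run: str, spectrum: Spectrum, record: SpectrumTruth) -> None:
        runs[run].append(spectrum)
        truth.spectra[run].append(record)

    for gene in truth.genes:
        for protease, rule in (("trypsin", TRYPSIN), ("lysarginase", LYSARGINASE)):
            peptides = digest(
                gene.mature_protein,
                rule,
                max_missed=config.max_missed,
                min_len=config.min_len,
                max_len=config.max_len,
                parent_id=gene.gene_id,
            )
            for pep in peptides:
                if rng.random() > config.peptide_detection_prob:
                    continue
                mods = apply_fixed_mods(pep.sequence, [CARBAMIDOMETHYL_C])
                frags14 = fragment_ions(pep.sequence, mods, "14N", (1,))
                keep = rng.random(len(frags14)) >= config.fragment_dropout_prob
                inten = rng.lognormal(0.0, config.intensity_sigma, len(frags14))
                emit_15n = rng.random() < config.n15_fraction
                run14 = f"{protease}_14N"
                title = f"{run14}_{counter[run14]:05d}"
                counter[run14] += 1
                emit(
                    run14,
                    _spectrum_from_fragments(
                        title,
                        np.array([f.mz for f, k in zip(frags14, keep) if k]),
                        inten[keep],
                        precursor_mz(pep.sequence, mods, "14N", 2),
                        rng,
                        config,
                        "14N",
                    ),
                    SpectrumTruth(
                        title, gene.gene_id, pep.sequence, pep.start, pep.end,
                        protease, "14N",
                    ),
                )
                if emit_15n:
                    frags15 = fragment_ions(pep.sequence, mods, "15N", (1,))
                    run15 = f"{protease}_15N"
                    title15 = f"{run15}_{counter[run15]:05d}"
                    counter[run15] += 1
                    emit(
                        run15,
                        _spectrum_from_fragments(
                            title15,
                            np.array([f.mz for f, k in zip(frags15, keep) if k]),
                            inten[keep],
                            precursor_mz(pep.sequence, mods, "15N", 2),
                            rng,
                            config,
                            "15N",
                        ),
                        SpectrumTruth(
                            title15, gene.gene_id, pep.sequence, pep.start,
                            pep.end, protease, "15N",
                        ),
                    )

    for gene in truth.genes:
        if not (gene.mis_start or gene.hidden):
            continue
        if rng.random() > config.nterm_evidence_fraction:
            continue
        picked = _nterm_peptide(gene, config)
        if picked is None:
            continue
        seq, end = picked
        mods = apply_fixed_mods(seq, [CARBAMIDOMETHYL_C, DIMETHYL_K])
        mods[0] = DIMETHYL_N_TERM
        frags = fragment_ions(seq, mods, "14N", (1,))
        keep = rng.random(len(frags)) >= config.fragment_dropout_prob
        inten = rng.lognormal(0.0, config.intensity_sigma, len(frags))
        title = f"nterm_{counter['nterm']:05d}"
        counter["nterm"] += 1
        emit(
            "nterm",
            _spectrum_from_fragments(
                title,
                np.array([f.mz for f, k in zip(frags, keep) if k]),
                inten[keep],
                precursor_mz(seq, mods, "14N", 2),
                rng,
                config,
                "14N",
            ),
            SpectrumTruth(title, gene.gene_id, seq, 1, end, "trypsin", "14N"),
        )
    return runs


@dataclass
class DemoDataset:
    """Paths of an emitted demo dataset plus its in-memory truth."""

    root: Path
    genome_fasta: Path
    annotation_gff3: Path
    mgf_paths: dict[str, Path]
    truth_json: Path
    config_yaml: Path
    truth: GroundTruth
    config: SyntheticConfig


def make_demo_dataset(
    path: str | Path, config: SyntheticConfig | None = None
) -> DemoDataset:
    """Write a complete, ready-to-run synthetic dataset into a directory.

    Emits the genome FASTA, annotation GFF3, five MGF runs, the ground
    truth manifest and a pipeline configuration, all deterministic for
    ``config.seed``.
    """
    config = config or SyntheticConfig()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genome, annotation, truth = generate_truth_set(config, rng)
    runs = simulate_spectra(truth, config, rng)

    genome_fasta = root / "genome.fasta"
    annotation_gff3 = root / "annotation.gff3"
    truth_json = root / "truth.json"
    config_yaml = root / "config.yaml"
    write_genome_fasta(genome, genome_fasta)
    write_annotation_gff3(annotation, annotation_gff3, genome.id)
    mgf_paths = {}
    for run, spectra in runs.items():
        mgf_paths[run] = root / f"{run}.mgf"
        write_mgf(spectra, mgf_paths[run])
    truth.to_json(truth_json)

    pipeline_cfg = PipelineConfig(
        genome=str(genome_fasta),
        annotation=str(annotation_gff3),
        mgf_trypsin_14n=str(mgf_paths["trypsin_14N"]),
        mgf_lysarginase_14n=str(mgf_paths["lysarginase_14N"]),
        mgf_trypsin_15n=str(mgf_paths["trypsin_15N"]),
        mgf_lysarginase_15n=str(mgf_paths["lysarginase_15N"]),
        mgf_nterm=str(mgf_paths["nterm"]),
        out_dir=str(root / "results"),
        min_len=config.min_len,
        max_len=config.max_len,
        max_missed=config.max_missed,
        seed=config.seed,
    )
    pipeline_cfg.to_yaml(config_yaml)

    return DemoDataset(
        root=root,
        genome_fasta=genome_fasta,
        annotation_gff3=annotation_gff3,
        mgf_paths=mgf_paths,
        truth_json=truth_json,
        config_yaml=config_yaml,
        truth=truth,
        config=config,
    )
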