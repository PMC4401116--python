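"""Ground-truthed simulator for dual-indexed two-fragment amplicon plates.

The generator emulates the study design the pipeline targets: 96-well
plates of arthropod specimens, each with one true 658-nt COI barcode that
is PCR-amplified as two overlapping sub-fragments (FC covering positions
[0, 307) and BR covering [225, 658), hence an 82-nt overlap), tagged with a
5-mer MID on both ends plus the amplification primers, and paired-end
sequenced at 300 nt from each end.

Beyond clean reads it injects the three artefact classes the pipeline must
discriminate:

* **contaminants** — a fraction of wells carries reads from another
  specimen's barcode (intra-sample contamination picked up before tagging,
  so contaminant reads carry the well's own MIDs);
* **chimeras** — with a per-read probability, wells holding at least two
  templates emit a two-parent crossover amplicon with a breakpoint drawn
  from the middle half of the fragment;
* **endosymbionts** — a fraction of wells co-amplifies a packaged synthetic
  "Wolbachia-like" template that is highly divergent from every reference.

Substitution errors are applied uniformly per base (no indels); qualities
are drawn from a truncated normal and are independent of the error process.
Every read's origin is recorded in a :class:`TruthTable` keyed by read id,
so parameter-recovery tests can score each stage exactly. All randomness
flows from one integer seed; identical configurations produce identical
output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import encode_bits, revcomp
from .demux import PrimerSet
from .io import (
    MidTable, Read, ReadPair, WellAssignment,
    write_fasta, write_fastq, write_mapping,
)

__all__ = [
    "SimConfig", "SpecimenTruth", "TruthTable", "SimResult",
    "generate_references", "default_primers", "default_mapping",
    "simulate", "write_simulation",
]

#: Classic Folmer COI barcoding primers used for the outer primer slots.
LCO1490 = "GGTCAACAAATCATAAAGATATTGG"
HCO2198 = "TAAACTTCAGGGTGACCAAAAAATCA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_WELLS_96 = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated experiment.

    The defaults reproduce the target design: two 96-well plates, 658-nt
    barcodes split into fragments spanning [0, 307) and [225, 658) (82-nt
    overlap), 300 x 2 paired-end reads, 50 read pairs per fragment per
    specimen, a 0.1% per-base substitution rate, 5% contaminated wells and
    a 2% chimeric-amplicon rate.
    """

    n_plates: int = 2
    wells_per_plate: int = 96
    barcode_length: int = 658
    fc_span: tuple[int, int] = (0, 307)
    br_span: tuple[int, int] = (225, 658)
    read_length: int = 300
    coverage: int = 50
    per_base_error: float = 0.001
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    contaminant_frac: float = 0.05
    contaminant_share: float = 0.30
    chimera_rate: float = 0.02
    endosymbiont_rate: float = 0.05
    endosymbiont_share: float = 0.20
    n_references: int = 32
    reference_min_div: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.wells_per_plate <= 96:
            raise ValueError("wells_per_plate must be in 1..96")
        (f0, f1), (b0, b1) = self.fc_span, self.br_span
        if not (f0 == 0 and b1 == self.barcode_length and f0 < b0 < f1 < b1):
            raise ValueError("fragment spans must overlap and tile the barcode")

    @property
    def overlap(self) -> int:
        return self.fc_span[1] - self.br_span[0]

    def span_for(self, fragment: str) -> tuple[int, int]:
        return self.fc_span if fragment == "FC" else self.br_span


@dataclass
class SpecimenTruth:
    specimen: str
    barcode: str
    label: str
    contaminant_label: str | None = None
    contaminant_barcode: str | None = None
    endosymbiont: bool = False


@dataclass
class TruthTable:
    """Ground truth: per-specimen templates and a per-read origin map.

    ``read_origins`` maps a read id stem to one of ``true``,
    ``contaminant``, ``endosymbiont`` or ``chimera``; for chimeric reads
    ``chimera_parents`` records the origins of the two parent templates.
    """

    specimens: dict[str, SpecimenTruth] = field(default_factory=dict)
    read_origins: dict[str, str] = field(default_factory=dict)
    chimera_parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    def origin_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for origin in self.read_origins.values():
            counts[origin] = counts.get(origin, 0) + 1
        return counts


@dataclass
class SimResult:
    config: SimConfig
    reads: dict[tuple[str, str], list[ReadPair]]  # (plate, fragment) -> pairs
    truth: TruthTable
    mapping: list[WellAssignment]
    references: list[tuple[str, str]]  # includes the endosymbiont template
    primers: PrimerSet


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _p_dist(a: str, b: str) -> float:
    aa = np.frombuffer(a.encode(), np.uint8)
    bb = np.frombuffer(b.encode(), np.uint8)
    return float(np.count_nonzero(aa != bb)) / len(aa)


def generate_references(
    n: int,
    length: int = 658,
    min_div: float = 0.05,
    seed: int = 0,
    max_tries: int = 100,
    label_prefix: str = "taxon",
) -> list[tuple[str, str]]:
    """Random reference barcodes with pairwise divergence >= ``min_div``.

    Rejection sampling; random sequences are far apart with overwhelming
    probability, so retries only matter for extreme ``min_div``.
    """
    if n < 1:
        raise ValueError("need at least one reference")
    rng = np.random.default_rng(seed)
    refs: list[str] = []
    while len(refs) < n:
        for _ in range(max_tries):
            cand = _random_seq(rng, length)
            if all(_p_dist(cand, r) >= min_div for r in refs):
                refs.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place reference {len(refs) + 1} at min_div={min_div}")
    return [(f"{label_prefix}{i + 1:03d}", s) for i, s in enumerate(refs)]


def default_primers() -> PrimerSet:
    """Folmer-style outer primers plus the published internal primers."""
    return PrimerSet(fc_forward=LCO1490, br_reverse=HCO2198)


def default_mapping(
    n_plates: int = 2,
    wells_per_plate: int = 96,
    mids: MidTable | None = None,
) -> list[WellAssignment]:
    """A plate layout encoding 96 wells with 20 MIDs per fragment.

    Columns 1-12 select the forward MID (list entries 1-12), rows A-H the
    reverse MID (entries 13-20), independently for each fragment's list, so
    every well has a unique (forward, reverse) combination.
    """
    mids = mids or MidTable()
    assignments = []
    for p in range(1, n_plates + 1):
        for w, well in enumerate(_WELLS_96[:wells_per_plate]):
            row, col = w // 12, w % 12
            for fragment in ("FC", "BR"):
                pool = mids.mids_for(fragment)
                assignments.append(WellAssignment(
                    plate=f"P{p}", well=well, fragment=fragment,
                    forward_mid=pool[col], reverse_mid=pool[12 + row],
                ))
    return assignments


def _concretize_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve degenerate positions to concrete bases compatible with the
    pattern (what an amplicon physically carries after synthesis)."""
    out = []
    for char in primer:
        bits = int(encode_bits(char)[0])
        choices = [b for i, b in enumerate("ACGT") if bits & (1 << i)]
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alts = _BASES[_BASES != arr[i]]
        arr[i] = alts[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


def _draw_quals(n: int, cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    q = rng.normal(cfg.quality_mean, cfg.quality_sd, size=n)
    return [int(x) for x in np.clip(np.rint(q), 2, 41)]


def simulate(
    cfg: SimConfig,
    references: list[tuple[str, str]] | None = None,
    mapping: list[WellAssignment] | None = None,
    primers: PrimerSet | None = None,
) -> SimResult:
    """Simulate paired-end FASTQ data and its truth table.

    References, mapping and primers default to :func:`generate_references`
    (seeded from the config), :func:`default_mapping` and
    :func:`default_primers`.
    """
    rng = np.random.default_rng(cfg.seed)
    primers = primers or default_primers()
    if references is None:
        references = generate_references(
            cfg.n_references, cfg.barcode_length, cfg.reference_min_div,
            seed=cfg.seed)
    mapping = mapping or default_mapping(cfg.n_plates, cfg.wells_per_plate)

    # the packaged endosymbiont template: synthetic, highly divergent
    endo_label = "Wolbachia-like"
    endo_rng = np.random.default_rng(cfg.seed + 10_007)
    while True:
        endo_seq = _random_seq(endo_rng, cfg.barcode_length)
        if all(_p_dist(endo_seq, s) >= 0.15 for _, s in references):
            break
    all_refs = references + [(endo_label, endo_seq)]

    concrete = {
        "FC": (_concretize_primer(primers.fc_forward, rng),
               _concretize_primer(primers.fc_reverse, rng)),
        "BR": (_concretize_primer(primers.br_forward, rng),
               _concretize_primer(primers.br_reverse, rng)),
    }
    tags: dict[tuple[str, str, str], WellAssignment] = {
        (wa.plate, wa.well, wa.fragment): wa for wa in mapping
    }
    wells = sorted({(wa.plate, wa.well) for wa in mapping})
    for plate, well in wells:
        for fragment in ("FC", "BR"):
            if (plate, well, fragment) not in tags:
                raise ValueError(f"mapping lacks {fragment} tags for {plate} {well}")

    truth = TruthTable()
    reads: dict[tuple[str, str], list[ReadPair]] = {}
    serial = 0
    for plate, well in wells:
        specimen = f"{plate}_{well}"
        label, barcode = references[int(rng.integers(len(references)))]
        st = SpecimenTruth(specimen=specimen, barcode=barcode, label=label)
        # templates present in this well: (origin, label, barcode, weight)
        templates = [("true", label, barcode)]
        weights = [1.0]
        if rng.random() < cfg.contaminant_frac and len(references) > 1:
            while True:
                clabel, cseq = references[int(rng.integers(len(references)))]
                if clabel != label:
                    break
            st.contaminant_label, st.contaminant_barcode = clabel, cseq
            templates.append(("contaminant", clabel, cseq))
            weights.append(cfg.contaminant_share)
            weights[0] -= cfg.contaminant_share
        if rng.random() < cfg.endosymbiont_rate:
            st.endosymbiont = True
            templates.append(("endosymbiont", endo_label, endo_seq))
            weights.append(cfg.endosymbiont_share)
            weights[0] -= cfg.endosymbiont_share
        truth.specimens[specimen] = st
        probs = np.array(weights) / sum(weights)

        for fragment in ("FC", "BR"):
            wa = tags[(plate, well, fragment)]
            lo, hi = cfg.span_for(fragment)
            fprimer, rprimer = concrete[fragment]
            pool = reads.setdefault((plate, fragment), [])
            for _ in range(cfg.coverage):
                chimeric = (len(templates) >= 2
                            and rng.random() < cfg.chimera_rate)
                if chimeric:
                    ia, ib = rng.choice(len(templates), size=2, replace=False,
                                        p=probs)
                    frag_a = templates[int(ia)][2][lo:hi]
                    frag_b = templates[int(ib)][2][lo:hi]
                    n = len(frag_a)
                    x = int(rng.integers(n // 4, 3 * n // 4))
                    insert = frag_a[:x] + frag_b[x:]
                    origin = "chimera"
                    parents = (templates[int(ia)][0], templates[int(ib)][0])
                else:
                    it = int(rng.choice(len(templates), p=probs))
                    origin = templates[it][0]
                    insert = templates[it][2][lo:hi]
                amplicon = (wa.forward_mid + fprimer + insert
                            + revcomp(rprimer) + revcomp(wa.reverse_mid))
                serial += 1
                stem = f"sim{serial:07d}_{specimen}_{fragment}"
                truth.read_origins[stem] = origin
                if origin == "chimera":
                    truth.chimera_parents[stem] = parents
                fwd_seq = _apply_errors(
                    amplicon[:cfg.read_length], cfg.per_base_error, rng)
                rev_seq = _apply_errors(
                    revcomp(amplicon)[:cfg.read_length], cfg.per_base_error, rng)
                pool.append(ReadPair(
                    forward=Read(id=stem, sequence=fwd_seq,
                                 qualities=_draw_quals(len(fwd_seq), cfg, rng)),
                    reverse=Read(id=stem, sequence=rev_seq,
                                 qualities=_draw_quals(len(rev_seq), cfg, rng)),
                ))
    return SimResult(config=cfg, reads=reads, truth=truth, mapping=mapping,
                     references=all_refs, primers=primers)


def write_simulation(result: SimResult, outdir) -> None:
    """Write FASTQ (R1/R2 per plate x fragment), the tag map, the reference
    FASTA (endosymbiont included) and a per-read truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (plate, fragment), pairs in sorted(result.reads.items()):
        write_fastq((p.forward for p in pairs),
                    outdir / f"{plate}_{fragment}_R1.fastq.gz")
        write_fastq((p.reverse for p in pairs),
                    outdir / f"{plate}_{fragment}_R2.fastq.gz")
    write_mapping(result.mapping, outdir / "mapping.tsv")
    write_fasta(result.references, outdir / "references.fasta")
    with open(outdir / "truth_reads.tsv", "w") as fh:
        fh.write("read_id\torigin\tparents\n")
        for stem, origin in result.truth.read_origins.items():
            parents = result.truth.chimera_parents.get(stem)
            fh.write(f"{stem}\t{origin}\t"
                     f"{'+'.join(parents) if parents else ''}\n")
    with open(outdir / "truth_specimens.tsv", "w") as fh:
        fh.write("specimen\tlabel\tbarcode\tcontaminant_label\tendosymbiont\n")
        for st in result.truth.specimens.values():
            fh.write(f"{st.specimen}\t{st.label}\t{st.barcode}\t"
                     f"{st.contaminant_label or ''}\t{int(st.endosymbiont)}\n")
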