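"""Synthetic data generators with serialized ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes and carries the planted truth needed to score that stage:

- :func:`make_transcriptome` — transcripts with planted 7TM receptor ORFs
  (hydrophobic 21-residue helices, positive-inside loop charge, seed-
  recognizable sequence), multi-TM non-receptor decoys that trip naive
  similarity searches, and ORF-free background transcripts;
- :func:`make_similarity_blocks` — block-structured p-valued edge lists;
- :func:`make_counts` — overdispersed 6-vs-6 replicate count tables with
  a planted sexually enriched subset and an abundance-correlated
  fold-change bias for the trend normalization to remove;
- :func:`make_dose_response` — sigmoidal concentration series with
  additive noise.

All generators are deterministic under their seed.  Sequence realism is
motif-level (composition and architecture), not evolutionary-simulation
level: enough to exercise the filter rules, not to mimic real receptor
families.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CountTable
from .io_formats import SequenceRecord
from .mining import Seed

# receptor and decoy compositions are kept disjoint (TM and loop alike)
# so cross-family local-alignment scores stay far above the exclusion
# E-value cutoff while both families remain hydrophobic enough to pass
# the hydropathy segment caller
_TM_RECEPTOR = "LIF"
_TM_DECOY = "AVC"
_LOOP_PLAIN = "STNQDE"
_LOOP_DECOY = "GPHY"
_CHARGED = "KKKKR"  # intracellular loop charge (positive-inside rule)

# synonymous codons (stops excluded); planted proteins avoid Met so that
# truncated ORFs have no internal in-frame ATG
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


@dataclass
class TranscriptomeTruth:
    receptor_ids: list[str]
    decoy_ids: list[str]
    background_ids: list[str]
    tm_segments: dict[str, list[tuple[int, int]]]  # protein-residue intervals
    completeness: dict[str, str]  # complete | truncated_5 | truncated_3

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class CountsTruth:
    enriched_ids: list[str]
    fold: float
    bias_slope: float
    bias_intercept: float
    nominal_log10_rpkm: dict[str, float]

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _choices(rng: np.random.RandomState, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.randint(0, len(alphabet), size=n))


def _mutate(rng: np.random.RandomState, seq: str, rate: float, alphabets: Sequence[str]) -> str:
    """Substitute positions at the given rate, each within its own alphabet.

    ``alphabets[i]`` is the allowed alphabet at position i; charged loop
    positions keep their charge so the orientation signal survives.
    """
    out = list(seq)
    hits = rng.random_sample(len(seq)) < rate
    for i in np.flatnonzero(hits):
        out[i] = alphabets[i][rng.randint(0, len(alphabets[i]))]
    return "".join(out)


def _receptor_architecture(
    rng: np.random.RandomState,
    n_tm: int = 7,
    n_tail: int = 25,
    loop_len: int = 10,
    c_tail: int = 20,
    charged_in: bool = True,
    tm_alphabet: str = _TM_RECEPTOR,
    loop_alphabet: str = _LOOP_PLAIN,
) -> tuple[str, list[str], list[tuple[int, int]]]:
    """Build (sequence, per-position allowed alphabets, TM intervals).

    Intracellular loops (odd loops counting the N-tail as loop 0) carry
    interleaved K/R; for ``charged_in=False`` the charge moves to the
    even loops instead, flipping the predicted orientation.
    """
    chars: list[str] = []
    alph: list[str] = []
    segs: list[tuple[int, int]] = []

    def emit(alphabet: str) -> None:
        chars.append(alphabet[rng.randint(0, len(alphabet))])
        alph.append(alphabet)

    def loop(length: int, loop_index: int) -> None:
        charged = (loop_index % 2 == 1) == charged_in
        for k in range(length):
            emit(_CHARGED if charged and k % 2 == 0 and k < 10 else loop_alphabet)

    def tm(length: int = 21) -> None:
        segs.append((len(chars), len(chars) + length))
        for _ in range(length):
            emit(tm_alphabet)

    loop(n_tail, 0)
    for t in range(n_tm):
        tm()
        if t < n_tm - 1:
            loop(loop_len, t + 1)
    loop(c_tail, n_tm)
    return "".join(chars), alph, segs


def _backtranslate(rng: np.random.RandomState, protein: str) -> str:
    return "".join(
        _CODONS[a][rng.randint(0, len(_CODONS[a]))] for a in protein
    )


def _stop_free_utr(rng: np.random.RandomState, n_codons: int) -> str:
    """Random UTR built from non-stop, non-ATG codons."""
    pool = [c for cods in _CODONS.values() for c in cods if c != "ATG"]
    return "".join(pool[rng.randint(0, len(pool))] for _ in range(n_codons))


def make_transcriptome(
    n_receptors: int = 12,
    n_decoys: int = 8,
    n_background: int = 50,
    orf_completeness_mix: tuple[float, float, float] = (0.75, 0.125, 0.125),
    seed: int = 0,
    n_gpcr_seeds: int = 10,
    n_decoy_seeds: int = 10,
    mutation_rate: float = 0.2,
) -> tuple[list[SequenceRecord], list[Seed], TranscriptomeTruth]:
    """Transcriptome with planted receptors, decoys and background.

    Receptors and the GPCR seed set are independently mutated copies of a
    common 7TM consensus; decoys and the non-receptor seed set derive from
    a 9-TM consensus over a disjoint hydrophobic alphabet, so decoys trip
    the naive similarity search but fail the exclusion rule.  Background
    transcripts carry no ORF of mining length.  The completeness mix is
    the (complete, 5'-truncated, 3'-truncated) fraction triple applied to
    receptors in order.
    """
    if not math.isclose(sum(orf_completeness_mix), 1.0, abs_tol=1e-9):
        raise ValueError("orf_completeness_mix must sum to 1")
    rng = np.random.RandomState(seed)

    r_seq, r_alph, r_segs = _receptor_architecture(rng, n_tm=7)
    # decoy consensus: more helices, disjoint composition -> weak cross-similarity
    d_seq, d_alph, _ = _receptor_architecture(
        rng, n_tm=9, tm_alphabet=_TM_DECOY, loop_alphabet=_LOOP_DECOY
    )

    seeds: list[Seed] = []
    for i in range(n_gpcr_seeds):
        p = _mutate(rng, r_seq, mutation_rate + 0.05, r_alph)
        seeds.append(Seed(SequenceRecord(f"seed_gpcr_{i}", p, "protein"), "gpcr_seed"))
    for i in range(n_decoy_seeds):
        p = _mutate(rng, d_seq, mutation_rate + 0.05, d_alph)
        seeds.append(Seed(SequenceRecord(f"seed_tm_{i}", p, "protein"), "non_gpcr_tm"))

    n_c = round(n_receptors * orf_completeness_mix[0])
    n_5 = round(n_receptors * orf_completeness_mix[1])
    completeness_plan = (
        ["complete"] * n_c
        + ["truncated_5"] * n_5
        + ["truncated_3"] * (n_receptors - n_c - n_5)
    )

    records: list[SequenceRecord] = []
    truth = TranscriptomeTruth([], [], [], {}, {})
    for i in range(n_receptors):
        rid = f"rcpt_{i:03d}"
        protein = _mutate(rng, r_seq, mutation_rate, r_alph)
        comp = completeness_plan[i]
        dna = _assemble_transcript(rng, protein, comp)
        records.append(SequenceRecord(rid, dna, "dna"))
        truth.receptor_ids.append(rid)
        truth.tm_segments[rid] = list(r_segs)
        truth.completeness[rid] = comp
    for i in range(n_decoys):
        did = f"decoy_{i:03d}"
        protein = _mutate(rng, d_seq, mutation_rate, d_alph)
        dna = _assemble_transcript(rng, protein, "complete")
        records.append(SequenceRecord(did, dna, "dna"))
        truth.decoy_ids.append(did)
    for i in range(n_background):
        bid = f"bkg_{i:03d}"
        # codon-structured but stop-salted: no reading frame carries a long ORF
        n_cod = int(rng.randint(150, 400))
        dna = _stop_free_utr(rng, n_cod)
        dna = _salt_with_stops(rng, dna)
        records.append(SequenceRecord(bid, dna, "dna"))
        truth.background_ids.append(bid)
    return records, seeds, truth


def _salt_with_stops(rng: np.random.RandomState, dna: str, every_nt: int = 120) -> str:
    """Insert stop codons so no frame (either strand) holds a long ORF."""
    stops = ["TAA", "TAG", "TGA"]
    out = list(dna)
    for start in range(0, len(out) - 9, every_nt):
        for frame_off in range(3):
            pos = start + frame_off * 3
            if pos + 3 <= len(out):
                out[pos : pos + 3] = stops[rng.randint(0, 3)]
        # reverse-strand stops: TTA at forward position reads TAA in reverse
        pos = start + 9
        if pos + 3 <= len(out):
            out[pos : pos + 3] = "TTA"
        pos = start + 12
        if pos + 3 <= len(out):
            out[pos : pos + 3] = "CTA"
        pos = start + 15
        if pos + 3 <= len(out):
            out[pos : pos + 3] = "TCA"
    return "".join(out)


def _assemble_transcript(rng: np.random.RandomState, protein: str, completeness: str) -> str:
    cds = _backtranslate(rng, protein)
    if completeness == "complete":
        utr5 = _stop_free_utr(rng, 9) + "TAA"  # in-frame stop right before ATG
        utr3 = _stop_free_utr(rng, 10)
        return utr5 + "ATG" + cds + "TAA" + utr3
    if completeness == "truncated_5":
        return cds[90:] + "TAA" + _stop_free_utr(rng, 10)  # edge-start ORF
    if completeness == "truncated_3":
        utr5 = _stop_free_utr(rng, 9) + "TAA"
        return utr5 + "ATG" + cds[: len(cds) - 90]
    raise ValueError(f"unknown completeness {completeness!r}")


# ---------------------------------------------------------------------------
# similarity blocks


def make_similarity_blocks(
    block_sizes: Sequence[int] = (6, 5, 4),
    within_p_law: tuple[float, float] = (1e-40, 1e-15),
    between_p_law: tuple[float, float] = (1e-8, 1.0),
    between_density: float = 0.3,
    seed: int = 0,
) -> tuple[list[tuple[str, str, float]], dict[str, int]]:
    """Block-structured edge list with log-uniform p-value laws.

    Within-block pairs all receive p drawn log-uniformly from
    ``within_p_law``; between-block pairs appear with ``between_density``
    and draw from ``between_p_law``.  Returns (edges, membership truth).
    """
    rng = np.random.RandomState(seed)

    def logu(lo: float, hi: float) -> float:
        return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))

    nodes: list[str] = []
    member: dict[str, int] = {}
    for b, size in enumerate(block_sizes):
        for k in range(size):
            name = f"b{b}_n{k}"
            nodes.append(name)
            member[name] = b
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(nodes):
        for b_node in nodes[i + 1 :]:
            if member[a] == member[b_node]:
                edges.append((a, b_node, logu(*within_p_law)))
            elif rng.random_sample() < between_density:
                edges.append((a, b_node, logu(*between_p_law)))
    return edges, member


# ---------------------------------------------------------------------------
# count tables


def make_counts(
    n_genes: int = 200,
    n_per_group: int = 6,
    baseline_log10_range: tuple[float, float] = (0.5, 3.0),
    n_enriched: int = 10,
    fold: float = 8.0,
    dispersion: float = 0.05,
    bias_slope: float = 0.411,
    bias_intercept: float = 2.29,
    seed: int = 0,
    enriched_ids: Sequence[str] | None = None,
    library_size_factor: float = 20.0,
) -> tuple[CountTable, CountsTruth]:
    """Negative-binomial 6-vs-6 count table with planted enrichment and bias.

    Baseline expected counts are log-uniform over ``baseline_log10_range``;
    planted enriched genes are multiplied by ``fold`` in the sexual group;
    an abundance-correlated bias of ``bias_slope * log10(RPKM) -
    bias_intercept`` log2 units (defaults: the published trend
    coefficients) is added to every gene's sexual log2 fold change,
    emulating the composition effect of highly expressed sexually
    enriched genes inflating the sexual RPKM denominator: most genes
    drift toward apparent asexual enrichment, more so at low abundance,
    giving the trend normalization structure to remove.  The profiled
    gene set is a small slice of each library: per-sample totals are
    ``library_size_factor`` times the reference-set expectation, so the
    planted enrichment does not distort the totals.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.RandomState(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    lengths = rng.randint(500, 3000, size=n_genes)
    mu = 10.0 ** rng.uniform(*baseline_log10_range, size=n_genes)

    if enriched_ids is None:
        enriched_idx = rng.choice(n_genes, size=n_enriched, replace=False)
        enriched_ids = [genes[i] for i in sorted(enriched_idx)]
    enriched_set = set(enriched_ids)

    total_nominal = mu.sum()
    rpkm_nom = 1e9 * mu / (lengths * total_nominal)
    log10_rpkm = np.log10(rpkm_nom)
    bias = bias_slope * log10_rpkm - bias_intercept

    mu_sex = mu * (2.0 ** bias)
    mu_sex = mu_sex * np.array([fold if g in enriched_set else 1.0 for g in genes])
    mu_asex = mu

    samples = [f"sex{i}" for i in range(n_per_group)] + [
        f"asex{i}" for i in range(n_per_group)
    ]
    groups = {s: ("sexual" if s.startswith("sex") else "asexual") for s in samples}

    def draw(mu_vec: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu_vec).astype(float)
        r = 1.0 / dispersion
        p = r / (r + mu_vec)
        return rng.negative_binomial(r, p).astype(float)

    cols = {}
    for s in samples:
        cols[s] = draw(mu_sex if groups[s] == "sexual" else mu_asex)
    counts = pd.DataFrame(cols, index=genes)
    background = (library_size_factor - 1.0) * total_nominal
    table = CountTable(
        genes=genes,
        gene_lengths=dict(zip(genes, (int(x) for x in lengths))),
        samples=samples,
        groups=groups,
        counts=counts,
        total_mapped={s: float(counts[s].sum() + background) for s in samples},
    )
    truth = CountsTruth(
        enriched_ids=list(enriched_ids),
        fold=fold,
        bias_slope=bias_slope,
        bias_intercept=bias_intercept,
        nominal_log10_rpkm=dict(zip(genes, map(float, log10_rpkm))),
    )
    return table, truth


def make_reads(
    references: Sequence[SequenceRecord],
    reads_per_gene: dict[str, int],
    read_length: int = 100,
    error_rate: float = 0.0,
    sample: str = "s1",
    seed: int = 0,
) -> list[SequenceRecord]:
    """Uniform substring reads with uniform substitution noise (one sample)."""
    rng = np.random.RandomState(seed)
    reads: list[SequenceRecord] = []
    bases = "ACGT"
    n = 0
    for ref in references:
        for _ in range(reads_per_gene.get(ref.id, 0)):
            if len(ref.seq) <= read_length:
                frag = ref.seq
            else:
                start = rng.randint(0, len(ref.seq) - read_length + 1)
                frag = ref.seq[start : start + read_length]
            if error_rate > 0:
                frag = list(frag)
                for i in np.flatnonzero(rng.random_sample(len(frag)) < error_rate):
                    frag[i] = bases[rng.randint(0, 4)]
                frag = "".join(frag)
            reads.append(SequenceRecord(f"{sample}/read{n}", frag, "dna"))
            n += 1
    return reads


# ---------------------------------------------------------------------------
# dose-response


def make_dose_response(
    ec50: float = 36.7e-9,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    concentrations: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    ligand: str = "NPY-8",
    receptor: str = "NPYR-1",
):
    """Sigmoidal concentration series with additive Gaussian noise.

    Responses are 4PL evaluations on the normalized-response scale,
    noised, then clipped to [0, 1] (a normalized response is a fraction).
    Default concentrations: eight half-log steps bracketing the EC50.
    Returns (series, truth dict).
    """
    from .assays import DoseResponseSeries

    if concentrations is None:
        concentrations = ec50 * 10.0 ** np.arange(-2.0, 2.0, 0.5)
    conc = np.asarray(list(concentrations), dtype=float)
    if len(conc) < 4 or np.any(conc <= 0):
        raise ValueError("need >= 4 positive concentrations")
    rng = np.random.RandomState(seed)
    points: list[tuple[float, float]] = []
    rep_ids: list[str] = []
    for rep in range(n_replicates):
        y = bottom + (top - bottom) / (
            1.0 + 10.0 ** (hill * (math.log10(ec50) - np.log10(conc)))
        ) if hill != 0 else np.full(len(conc), (top + bottom) / 2.0)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=len(conc))
        y = np.clip(y, 0.0, 1.0)
        points.extend(zip(map(float, conc), map(float, y)))
        rep_ids.extend([f"rep{rep}"] * len(conc))
    series = DoseResponseSeries(ligand, receptor, points, rep_ids)
    truth = {"ec50": ec50, "hill": hill, "top": top, "bottom": bottom}
    return series, truth
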