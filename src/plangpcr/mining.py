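"""Genome-wide 7TM receptor mining.

The pipeline stages mirror standard receptor-repertoire curation:

1. six-frame ORF discovery on assembled transcripts, with end-of-ORF
   curation flags (upstream in-frame stop near the start codon, terminal
   stop codon inside the contig);
2. similarity search of candidate proteins against a seed set of known
   receptors, with Karlin–Altschul E-values from local-alignment scores;
3. an exclusion rule removing candidates whose strongest similarities are
   to non-receptor transmembrane proteins (ion channels, transporters);
4. a seven-transmembrane topology filter based on Kyte–Doolittle
   hydropathy and the positive-inside rule, applied only to candidates
   with confidently complete ORFs;
5. recursion: retained candidates join the seed set and mining repeats
   until the retained set reaches a fixpoint.

The topology predictor is a self-contained hydropathy model; externally
computed topology tables can be supplied to :func:`mine` to override it
per candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import SequenceRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0, "*": 0.0,
}

#: Karlin-Altschul (lambda, K) pairs for supported scoring systems,
#: keyed by (matrix, gap_open, gap_extend); gap costs follow the BLAST
#: convention (cost of a length-L gap = open + L * extend).
KARLIN_ALTSCHUL_PARAMS = {
    ("BLOSUM62", 11, 1): (0.267, 0.041),
    ("BLOSUM62", 10, 1): (0.243, 0.024),
    ("BLOSUM62", 0, 0): (0.3176, 0.134),  # ungapped
}


@dataclass(frozen=True)
class OrfAnnotation:
    """A maximal open reading frame on one strand/frame of a transcript.

    ``start``/``end`` are 0-based half-open offsets on the forward strand
    of the transcript; ``frame`` is 1..3 (forward) or -1..-3 (reverse
    complement).  The terminal stop codon, when present, is included in
    the interval.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    n_term_ok: bool = False
    c_term_ok: bool = False
    orf_confident: bool = False

    def __post_init__(self) -> None:
        if not (self.end > self.start):
            raise ValueError("ORF end must exceed start")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a codon multiple")
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if self.orf_confident != (self.n_term_ok and self.c_term_ok):
            raise ValueError("orf_confident must equal n_term_ok AND c_term_ok")


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    target_id: str
    target_class: str  # gpcr_seed | non_gpcr_tm | other
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


@dataclass(frozen=True)
class TopologyPrediction:
    protein_id: str
    tm_segments: tuple[tuple[int, int], ...]
    n_terminus_side: str  # "out" | "in"
    c_terminus_side: str

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.tm_segments:
            if s <= prev_end:
                raise ValueError("TM segments must be ascending and non-overlapping")
            if e <= s:
                raise ValueError("empty TM segment")
            prev_end = e - 1
        expected_c = (
            self.n_terminus_side
            if len(self.tm_segments) % 2 == 0
            else ("in" if self.n_terminus_side == "out" else "out")
        )
        if self.c_terminus_side != expected_c:
            raise ValueError("c_terminus_side inconsistent with segment parity")

    @property
    def n_segments(self) -> int:
        return len(self.tm_segments)


@dataclass
class ReceptorCandidate:
    protein: SequenceRecord
    orf: OrfAnnotation
    topology: TopologyPrediction | None = None
    hits: list[SimilarityHit] = field(default_factory=list)
    status: str = "retained"  # retained | excluded_similarity | excluded_topology
    round_admitted: int | None = None


@dataclass(frozen=True)
class Seed:
    """A seed protein with its class tag (gpcr_seed / non_gpcr_tm / other)."""

    record: SequenceRecord
    target_class: str = "gpcr_seed"


@dataclass(frozen=True)
class MiningParams:
    min_aa_len: int = 200
    upstream_window_nt: int = 90
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    admit_e: float = 1e-3
    top_k: int = 50
    e_cut: float = 1e-10
    min_fraction: float = 0.5
    tm_window: int = 19
    hydropathy_cut: float = 1.6
    max_rounds: int = 10


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_orfs(transcript: SequenceRecord, min_aa_len: int) -> list[OrfAnnotation]:
    """All maximal ORFs in all six frames with translated length >= ``min_aa_len``.

    An ORF runs from an ATG — or from the contig edge when the frame has no
    stop codon before the first possible start — to a stop codon (included)
    or the contig edge.  Coordinates are reported on the forward strand.
    """
    if transcript.alphabet != "dna":
        raise ValueError("find_orfs requires a dna-alphabet transcript")
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    n = len(transcript.seq)
    orfs: list[OrfAnnotation] = []
    for strand in (1, -1):
        s = transcript.seq if strand == 1 else _revcomp(transcript.seq)
        for off in range(3):
            n_codons = (n - off) // 3
            if n_codons == 0:
                continue
            codons = [s[off + 3 * i : off + 3 * i + 3] for i in range(n_codons)]
            seg_start = 0  # codon index where the current stop-free segment begins
            at_edge = True  # segment touches the 5' contig edge of this frame
            i = 0
            while i <= n_codons:
                is_stop = i < n_codons and codons[i] in STOP_CODONS
                if is_stop or i == n_codons:
                    seg = range(seg_start, i)
                    start_codon = None
                    for j in seg:
                        if codons[j] == "ATG":
                            start_codon = j
                            break
                    # a 5'-truncated ORF (contig-edge start, no ATG) still
                    # needs its 3' anchor: a terminal stop codon
                    if start_codon is None and at_edge and len(seg) > 0 and is_stop:
                        start_codon = seg_start
                    if start_codon is not None:
                        aa_len = i - start_codon  # stop codon excluded
                        if aa_len >= min_aa_len:
                            lo = off + 3 * start_codon
                            hi = off + 3 * (i + 1) if is_stop else off + 3 * i
                            if strand == 1:
                                start, end = lo, hi
                            else:
                                start, end = n - hi, n - lo
                            orfs.append(
                                OrfAnnotation(
                                    transcript_id=transcript.id,
                                    frame=strand * (off + 1),
                                    start=start,
                                    end=end,
                                )
                            )
                    seg_start = i + 1
                    at_edge = False
                i += 1
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


def _strand_local(transcript: SequenceRecord, orf: OrfAnnotation) -> tuple[str, int, int]:
    """Return (strand sequence, local start, local end) for an ORF."""
    n = len(transcript.seq)
    if orf.frame > 0:
        return transcript.seq, orf.start, orf.end
    return _revcomp(transcript.seq), n - orf.end, n - orf.start


def orf_nucleotides(transcript: SequenceRecord, orf: OrfAnnotation) -> str:
    s, lo, hi = _strand_local(transcript, orf)
    return s[lo:hi]

def orf_protein(transcript: SequenceRecord, orf: OrfAnnotation) -> SequenceRecord:
    """Translate an ORF; the trailing stop, if any, is stripped."""
    nt = orf_nucleotides(transcript, orf)
    aa = str(Seq(nt).translate())
    aa = aa.rstrip("*")
    return SequenceRecord(f"{transcript.id}", aa.replace("*", "X"), "protein")


def flag_orf_ends(
    transcript: SequenceRecord, orf: OrfAnnotation, upstream_window_nt: int = 90
) -> OrfAnnotation:
    """Set the end-curation flags on an ORF.

    ``n_term_ok``: the ORF starts at an ATG and an in-frame stop codon lies
    within ``upstream_window_nt`` nucleotides upstream of it — evidence the
    true start was captured.  ``c_term_ok``: the ORF terminates at a stop
    codon inside the transcript.  ``orf_confident`` is the conjunction.
    """
    if upstream_window_nt < 0:
        raise ValueError("upstream_window_nt must be >= 0")
    if not (0 <= orf.start < orf.end <= len(transcript.seq)):
        raise ValueError("ORF does not lie within the transcript")
    s, lo, hi = _strand_local(transcript, orf)

    c_ok = s[hi - 3 : hi] in STOP_CODONS
    n_ok = False
    if s[lo : lo + 3] == "ATG":
        pos = lo - 3
        while pos >= 0 and lo - pos <= upstream_window_nt:
            if s[pos : pos + 3] in STOP_CODONS:
                n_ok = True
                break
            pos -= 3
    return replace(
        orf, n_term_ok=n_ok, c_term_ok=c_ok, orf_confident=n_ok and c_ok
    )


# ---------------------------------------------------------------------------
# similarity search


def _make_aligner(matrix_name: str, gap_open: int, gap_extend: int):
    from Bio import Align
    from Bio.Align import substitution_matrices

    try:
        matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from None
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: length-L gap costs open + L*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def search_seeds(
    query_proteins: Sequence[SequenceRecord],
    seed_proteins: Sequence[Seed],
    gap_open: int = 11,
    gap_extend: int = 1,
    matrix_name: str = "BLOSUM62",
) -> list[SimilarityHit]:
    """Local-alignment hits of each query against all seeds.

    E-values follow the Karlin–Altschul statistics for the named scoring
    system, with effective search space = query length x total database
    length.  Hits are sorted ascending by (e_value, target_id).
    """
    key = (matrix_name, gap_open, gap_extend)
    if key not in KARLIN_ALTSCHUL_PARAMS:
        raise ValueError(
            f"no Karlin-Altschul parameters for {matrix_name} "
            f"with gaps ({gap_open}, {gap_extend})"
        )
    lam, k_const = KARLIN_ALTSCHUL_PARAMS[key]
    if not seed_proteins:
        return []
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    db_len = sum(len(s.record.seq) for s in seed_proteins)
    hits: list[SimilarityHit] = []
    for q in query_proteins:
        qseq = q.seq.replace("*", "X")
        for seed in seed_proteins:
            score = aligner.score(qseq, seed.record.seq.replace("*", "X"))
            bit = (lam * score - math.log(k_const)) / math.log(2.0)
            e = len(q.seq) * db_len * 2.0 ** (-bit)
            e = max(e, 1e-300)
            hits.append(
                SimilarityHit(
                    query_id=q.id,
                    target_id=seed.record.id,
                    target_class=seed.target_class,
                    bit_score=bit,
                    e_value=e,
                )
            )
    hits.sort(key=lambda h: (h.e_value, h.target_id))
    return hits


def exclusion_filter(
    hits: Sequence[SimilarityHit],
    top_k: int = 50,
    e_cut: float = 1e-10,
    min_fraction: float = 0.5,
) -> str:
    """Non-receptor exclusion rule.

    ``"exclude"`` iff, among the ``top_k`` best hits (all hits if fewer),
    the fraction that are non-receptor transmembrane proteins at
    e_value < ``e_cut`` reaches ``min_fraction``.  An empty hit list keeps
    the candidate (vacuous rule).
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in [0, 1]")
    if not hits:
        return "keep"
    top = sorted(hits, key=lambda h: (h.e_value, h.target_id))[:top_k]
    n_bad = sum(
        1 for h in top if h.target_class == "non_gpcr_tm" and h.e_value < e_cut
    )
    return "exclude" if n_bad / len(top) >= min_fraction else "keep"


# ---------------------------------------------------------------------------
# topology


def predict_topology(
    protein: SequenceRecord, window: int = 19, hydropathy_cut: float = 1.6
) -> TopologyPrediction:
    """Sliding-window Kyte-Doolittle transmembrane-segment prediction.

    Maximal runs of window-mean hydropathy above ``hydropathy_cut`` become
    TM segments; runs separated by fewer than 4 residues are merged, and
    each segment is trimmed/padded toward the canonical 21-residue helix
    length.  Orientation follows the positive-inside rule: the loop side
    with the greater summed lysine+arginine count is called intracellular.
    """
    if protein.alphabet != "protein":
        raise ValueError("predict_topology requires a protein sequence")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    seq = protein.seq.upper()
    n = len(seq)
    if n < window:
        return TopologyPrediction(protein.id, (), "out", "out")

    hyd = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    means = np.convolve(hyd, np.ones(window) / window, mode="valid")
    half = window // 2
    centers_above = np.flatnonzero(means > hydropathy_cut) + half

    # maximal runs of consecutive above-threshold centers
    raw: list[list[int]] = []
    for c in centers_above:
        if raw and c == raw[-1][1] + 1:
            raw[-1][1] = c
        else:
            raw.append([c, c])
    # merge runs separated by < 4 residues
    merged: list[list[int]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] - 1 < 4:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # resize toward canonical 21-residue helices, clamped to the protein
    segments: list[tuple[int, int]] = []
    for s, e in merged:
        mid = (s + e) // 2
        lo = max(0, mid - 10)
        hi = min(n, lo + 21)
        lo = max(0, hi - 21)
        segments.append((lo, hi))
    # enforce non-overlap after padding: split at the midpoint
    fixed: list[tuple[int, int]] = []
    for seg in segments:
        if fixed and seg[0] < fixed[-1][1]:
            b = (fixed[-1][1] + seg[0]) // 2
            prev = fixed[-1]
            if prev[0] < b and b < seg[1]:
                fixed[-1] = (prev[0], b)
                fixed.append((b, seg[1]))
            continue
        fixed.append(seg)

    n_term = _orient_positive_inside(seq, fixed)
    c_term = n_term if len(fixed) % 2 == 0 else ("in" if n_term == "out" else "out")
    return TopologyPrediction(protein.id, tuple(fixed), n_term, c_term)


def _orient_positive_inside(seq: str, segments: list[tuple[int, int]]) -> str:
    """Choose the N-terminus side maximizing K+R on the intracellular loops."""
    if not segments:
        return "out"
    bounds = [0] + [b for seg in segments for b in seg] + [len(seq)]
    loops = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(len(segments) + 1)]
    charge = [sum(1 for a in seq[lo:hi] if a in "KR") for lo, hi in loops]
    even = sum(charge[0::2])  # N-tail side
    odd = sum(charge[1::2])
    # N-terminus "out" puts odd loops inside; ties default to "out"
    return "out" if odd >= even else "in"


def topology_filter(candidate: ReceptorCandidate) -> ReceptorCandidate:
    """Exclude confidently complete ORFs lacking canonical 7TM topology.

    Candidates without a confident ORF are never excluded on topology:
    a truncated protein cannot be expected to show all seven helices.
    Status transitions are monotone — an already excluded candidate keeps
    its status.
    """
    if candidate.status != "retained":
        return candidate
    if candidate.topology is None:
        raise ValueError("topology_filter requires a populated topology")
    if not candidate.orf.orf_confident:
        return candidate
    topo = candidate.topology
    ok = (
        topo.n_segments == 7
        and topo.n_terminus_side == "out"
        and topo.c_terminus_side == "in"
    )
    if not ok:
        candidate.status = "excluded_topology"
    return candidate


# ---------------------------------------------------------------------------
# recursive mining


def mine(
    transcriptome: Sequence[SequenceRecord],
    seeds: Sequence[Seed],
    params: MiningParams = MiningParams(),
    topology_overrides: Mapping[str, TopologyPrediction] | None = None,
) -> dict[str, ReceptorCandidate]:
    """Iterated receptor mining to a fixpoint.

    Each round: ORF discovery -> similarity search against the seed set
    plus previously retained candidates -> exclusion rule -> topology
    filter.  Rounds repeat until the retained set is unchanged; candidates
    once excluded are never re-admitted within a pass.

    ``topology_overrides`` maps transcript ids to externally computed
    topology predictions (e.g. imported curation tables); they replace the
    in-repo hydropathy prediction for those candidates.

    Returns a mapping of transcript id to its candidate (admitted
    candidates only), with per-candidate provenance.
    """
    overrides = topology_overrides or {}

    # every qualifying ORF is a potential candidate; the similarity search
    # decides which ORF represents a transcript (spurious frames — e.g. a
    # long stop-free stretch on the opposite strand — carry no seed
    # similarity and lose to the true coding frame)
    orfs_by_tr: dict[str, list[tuple[SequenceRecord, OrfAnnotation]]] = {}
    for tr in transcriptome:
        found = find_orfs(tr, params.min_aa_len)
        if not found:
            continue
        found.sort(key=lambda o: (-(o.end - o.start), o.start))
        entries = []
        for k, orf in enumerate(found[:3]):  # 3 longest frames suffice
            orf = flag_orf_ends(tr, orf, params.upstream_window_nt)
            protein = orf_protein(tr, orf)
            entries.append((replace(protein, id=f"{tr.id}\x00{k}"), orf))
        orfs_by_tr[tr.id] = entries

    candidates: dict[str, ReceptorCandidate] = {}
    retained_prev: set[str] = set()
    history: list[int] = []
    for round_no in range(1, params.max_rounds + 1):
        database = list(seeds) + [
            Seed(candidates[cid].protein, "gpcr_seed")
            for cid in sorted(retained_prev)
        ]
        new_ids = [tid for tid in orfs_by_tr if tid not in candidates]
        queries = [p for tid in new_ids for p, _ in orfs_by_tr[tid]]
        all_hits = search_seeds(
            queries, database, params.gap_open, params.gap_extend, params.matrix_name
        )
        hits_by_query: dict[str, list[SimilarityHit]] = {q.id: [] for q in queries}
        for h in all_hits:
            hits_by_query[h.query_id].append(h)

        for tid in new_ids:
            # the transcript's candidate ORF: most significant seed hit
            scored = []
            for k, (protein_k, orf_k) in enumerate(orfs_by_tr[tid]):
                hk = hits_by_query[protein_k.id]
                best_e = hk[0].e_value if hk else float("inf")
                scored.append((best_e, k, protein_k, orf_k, hk))
            scored.sort(key=lambda t: (t[0], t[1]))
            best_e, _, protein, orf, hits = scored[0]
            if best_e > params.admit_e:
                continue  # not admitted this round; may be admitted later
            protein = replace(protein, id=tid)
            hits = [replace(h, query_id=tid) for h in hits]
            cand = ReceptorCandidate(
                protein=protein, orf=orf, hits=hits, round_admitted=round_no
            )
            if exclusion_filter(
                hits, params.top_k, params.e_cut, params.min_fraction
            ) == "exclude":
                cand.status = "excluded_similarity"
            else:
                cand.topology = overrides.get(
                    tid,
                    predict_topology(protein, params.tm_window, params.hydropathy_cut),
                )
                cand = topology_filter(cand)
            candidates[tid] = cand

        retained_now = {
            cid for cid, c in candidates.items() if c.status == "retained"
        }
        history.append(len(retained_now))
        if retained_now == retained_prev:
            return candidates
        retained_prev = retained_now
    raise RuntimeError(
        f"mining did not converge after {params.max_rounds} rounds; "
        f"retained-set sizes per round: {history}"
    )
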