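"""Per-pair divergence: protein alignment, codon back-translation, dN/dS.

The pipeline aligns the two proteins globally (Needleman-Wunsch with affine
gaps, BLOSUM62, free end gaps — the defaults of the classic ``needle``
program), threads the coding sequences through the protein alignment codon by
codon, and estimates synonymous and nonsynonymous divergence with the
Nei-Gojobori counting method plus Jukes-Cantor multiple-hit correction:

    dS = -(3/4) ln(1 - (4/3) pS),   pS = Sd / S

and likewise for dN, where S is the mean number of synonymous sites of the two
rows (per codon, the fraction of single-base changes that are synonymous) and
Sd/Nd partition the observed differences by averaging over all minimal
substitution paths between differing codons, excluding paths through stop
codons.  omega = dN/dS is left undefined when dS = 0.

Externally computed dN/dS tables (e.g. from a maximum-likelihood estimator)
can be imported instead via :func:`import_divergence_table`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CODON = "---"

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
BASES = "ACGT"


class DivergenceError(ValueError):
    pass


# --------------------------------------------------------------------------
# protein alignment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinAlignment:
    aligned1: str
    aligned2: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned1) != len(self.aligned2):
            raise DivergenceError("aligned rows differ in length")
        for a, b in zip(self.aligned1, self.aligned2):
            if a == "-" and b == "-":
                raise DivergenceError("alignment contains an all-gap column")


def _scoring_matrix(name: str):
    mat = substitution_matrices.load(name)
    if "X" in mat.alphabet:
        # unknown residues are scored 0 against everything
        xi = mat.alphabet.index("X")
        mat[xi, :] = 0.0
        mat[:, xi] = 0.0
    return mat


def _validate_protein(seq: str, which: str) -> None:
    if not seq:
        raise DivergenceError(f"{which}: empty protein sequence")
    allowed = set(AMINO_ACIDS + "X")
    for i, c in enumerate(seq):
        if c not in allowed:
            raise DivergenceError(f"{which}: illegal residue {c!r} at position {i}")


def global_protein_align(
    seq1: str,
    seq2: str,
    scoring: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ProteinAlignment:
    """Optimal global alignment with affine gaps and free end gaps.

    A gap of length L costs ``gap_open + gap_extend * L``; end gaps are not
    penalized.  The traceback is deterministic (the aligner's first co-optimal
    alignment).
    """
    _validate_protein(seq1, "seq1")
    _validate_protein(seq2, "seq2")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _scoring_matrix(scoring)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.end_gap_score = 0.0
    alignment = aligner.align(seq1, seq2)[0]
    return ProteinAlignment(
        aligned1=str(alignment[0]), aligned2=str(alignment[1]), score=alignment.score
    )


# --------------------------------------------------------------------------
# codon alignment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    row1: str
    row2: str

    def __post_init__(self) -> None:
        if len(self.row1) != len(self.row2) or len(self.row1) % 3:
            raise DivergenceError("codon alignment rows must share a length divisible by 3")

    def codons(self):
        for i in range(0, len(self.row1), 3):
            yield self.row1[i : i + 3], self.row2[i : i + 3]


def _strip_terminal_stop(cds: str, protein: str) -> str:
    if len(cds) == 3 * (len(protein) + 1) and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def _check_cds(cds: str, protein: str, which: str) -> str:
    cds = _strip_terminal_stop(cds.upper(), protein)
    if len(cds) != 3 * len(protein):
        raise DivergenceError(
            f"{which}: CDS length {len(cds)} does not match 3 x protein length {len(protein)}"
        )
    for i in range(len(protein)):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            raise DivergenceError(f"{which}: internal stop codon at codon index {i}")
        aa = CODON_TO_AA.get(codon)
        if protein[i] == "X" or (aa is None and any(b not in BASES for b in codon)):
            continue  # ambiguous residue or base: tolerated, skipped downstream
        if aa != protein[i]:
            raise DivergenceError(
                f"{which}: translation mismatch at codon index {i} "
                f"({codon} -> {aa}, protein has {protein[i]})"
            )
    return cds


def backtranslate_alignment(
    alignment: ProteinAlignment, cds1: str, cds2: str
) -> CodonAlignment:
    """Expand a protein alignment to codons, gaps becoming ``---`` triplets."""
    prot1 = alignment.aligned1.replace("-", "")
    prot2 = alignment.aligned2.replace("-", "")
    cds1 = _check_cds(cds1, prot1, "cds1")
    cds2 = _check_cds(cds2, prot2, "cds2")
    rows = []
    for aligned, cds in ((alignment.aligned1, cds1), (alignment.aligned2, cds2)):
        out, k = [], 0
        for aa in aligned:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(row1=rows[0], row2=rows[1])


# --------------------------------------------------------------------------
# Nei-Gojobori counting estimator
# --------------------------------------------------------------------------


def _syn_fraction(codon: str) -> float:
    """Number of synonymous single-base changes / 3 possible changes per site, summed."""
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = sum(
            1
            for b in BASES
            if b != codon[pos]
            and CODON_TO_AA.get(codon[:pos] + b + codon[pos + 1 :]) == aa
        )
        total += syn / 3.0
    return total


_SYN_SITES = {c: _syn_fraction(c) for c in SENSE_CODONS}


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged over all orderings of the differing positions with equal weight;
    orderings passing through a stop codon are excluded (if every ordering
    does, all are kept and stop steps count as nonsynonymous).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur, syn, non, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TO_AA.get(cur) is not None and CODON_TO_AA.get(nxt) == CODON_TO_AA.get(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        paths.append((syn, non, blocked))
    valid = [(s, n) for s, n, b in paths if not b]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


@dataclass(frozen=True)
class DivergenceEstimate:
    dn: float | None
    ds: float | None
    omega: float | None
    n_sites: float = 0.0
    s_sites: float = 0.0
    nd: float = 0.0
    sd: float = 0.0
    n_codons: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-p / 0.75)


def ng86_divergence(alignment: CodonAlignment) -> DivergenceEstimate:
    """Nei-Gojobori dN/dS with Jukes-Cantor correction on a codon alignment.

    Codon columns containing gaps, ambiguous bases, or stop codons in either
    row are excluded from both site and difference counts.
    """
    s1 = s2 = sd = nd = 0.0
    n_codons = 0
    for c1, c2 in alignment.codons():
        if c1 not in _SYN_SITES or c2 not in _SYN_SITES:
            continue
        n_codons += 1
        s1 += _SYN_SITES[c1]
        s2 += _SYN_SITES[c2]
        if c1 != c2:
            key = (c1, c2) if c1 <= c2 else (c2, c1)
            if key not in _PAIR_CACHE:
                _PAIR_CACHE[key] = _path_counts(*key)
            dsd, dnd = _PAIR_CACHE[key]
            sd += dsd
            nd += dnd
    if n_codons == 0:
        raise DivergenceError("no comparable codon columns")
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    flags = []
    if ds is None or dn is None:
        flags.append("saturated")
    omega = None
    if dn is not None and ds is not None:
        if ds > 0:
            omega = dn / ds
        else:
            flags.append("omega_undefined")
    return DivergenceEstimate(
        dn=dn,
        ds=ds,
        omega=omega,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        n_codons=n_codons,
        flags=tuple(flags),
    )


# --------------------------------------------------------------------------
# external tables
# --------------------------------------------------------------------------


def import_divergence_table(source) -> dict[tuple[str, str], DivergenceEstimate]:
    """Load an externally computed per-pair dN/dS table (TSV: gene1 gene2 dN dS)."""
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"gene1", "gene2", "dN", "dS"}
    missing = required - set(df.columns)
    if missing:
        raise DivergenceError(f"divergence table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], DivergenceEstimate] = {}
    for idx, row in df.iterrows():
        try:
            dn, ds = float(row["dN"]), float(row["dS"])
        except (TypeError, ValueError):
            raise DivergenceError(f"non-numeric dN/dS in row {idx + 1}") from None
        flags: tuple[str, ...] = ()
        omega: float | None = None
        if ds > 0:
            omega = dn / ds
        else:
            flags = ("omega_undefined",)
        key = tuple(sorted((str(row["gene1"]), str(row["gene2"]))))
        out[key] = DivergenceEstimate(dn=dn, ds=ds, omega=omega, flags=flags)
    return out
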