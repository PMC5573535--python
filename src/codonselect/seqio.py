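"""Codon alignments, trees, masks, and codon frequency schemes.

In-frame coding alignments are stored as integer matrices over the 61 sense
codons of the standard genetic code; gaps and ambiguous triplets are encoded
as missing data (-1) rather than dropped, so site counts and coordinates are
preserved. All user-facing codon coordinates are 1-based and refer to the
unmasked gene, even after masking (e.g. a tandem-repeat region excluded
before analysis).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "TCAG"


class AlignmentError(ValueError):
    """Raised when a coding alignment violates frame/stop/name invariants."""


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A codon -> amino-acid mapping restricted to sense codons.

    Built from Biopython's codon tables; the default (table 1) has exactly
    61 sense codons, and stop codons are excluded from every downstream rate
    computation.
    """

    code_id: int
    codon_to_aa: dict
    stop_codons: frozenset
    sense_codons: tuple

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_table_id(1)

    @classmethod
    def from_table_id(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        all_codons = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
        stops = frozenset(table.stop_codons)
        sense = tuple(c for c in all_codons if c not in stops)
        mapping = {c: table.forward_table[c] for c in sense}
        return cls(code_id=table_id, codon_to_aa=mapping, stop_codons=stops,
                   sense_codons=sense)

    def __post_init__(self):
        if self.code_id == 1 and len(self.sense_codons) != 61:
            raise ValueError("standard code must have 61 sense codons")

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        """Index of a sense codon in the canonical TCAG ordering."""
        return self._index_map()[codon]

    def _index_map(self) -> dict:
        # cached on the instance dict despite frozen dataclass
        m = self.__dict__.get("_idx")
        if m is None:
            m = {c: i for i, c in enumerate(self.sense_codons)}
            object.__setattr__(self, "_idx", m)
        return m

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon_index: int) -> str:
        return self.codon_to_aa[self.sense_codons[codon_index]]


STANDARD_CODE = GeneticCode.standard()

MISSING = -1


@dataclass
class CodonAlignment:
    """An aligned set of in-frame coding sequences.

    ``codons[t, s]`` holds the sense-codon index of taxon ``t`` at alignment
    column ``s`` (or -1 for gap/ambiguity). ``site_index`` maps each stored
    column to its 1-based position in the unmasked gene, so reports keep gene
    numbering after masking.
    """

    taxa: list
    codons: np.ndarray
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)
    site_index: np.ndarray = None

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise AlignmentError("codon matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        if self.site_index is None:
            self.site_index = np.arange(1, self.codons.shape[1] + 1)
        self.site_index = np.asarray(self.site_index, dtype=np.int64)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    def subset_taxa(self, names) -> "CodonAlignment":
        idx = [self.taxa.index(n) for n in names]
        return CodonAlignment(list(names), self.codons[idx].copy(), self.code,
                              self.site_index.copy())

    def to_strings(self) -> dict:
        out = {}
        for t, row in zip(self.taxa, self.codons):
            out[t] = "".join(self.code.sense_codons[c] if c >= 0 else "---"
                             for c in row)
        return out


def _encode_sequence(name: str, seq: str, code: GeneticCode,
                     drop_terminal_stop: bool = True):
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise AlignmentError(
            f"sequence length of taxon '{name}' ({len(seq)} nt) is not divisible by 3")
    n = len(seq) // 3
    row = np.full(n, MISSING, dtype=np.int64)
    for i in range(n):
        codon = seq[3 * i:3 * i + 3]
        if codon in code.stop_codons:
            if drop_terminal_stop and i == n - 1:
                continue
            raise AlignmentError(
                f"internal stop codon {codon} in taxon '{name}' at codon {i + 1}")
        if all(b in "ACGT" for b in codon):
            row[i] = code.index(codon)
    return row


def read_codon_fasta(path, code: GeneticCode = STANDARD_CODE) -> CodonAlignment:
    """Read an aligned, in-frame FASTA into a :class:`CodonAlignment`.

    Validates frame (length divisible by 3), equal lengths, unique taxon
    names, and absence of internal stop codons. A terminal stop column (stop
    or gap in every taxon) is dropped.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise AlignmentError(f"duplicate taxon names: {', '.join(dups)}")
    for r in records:  # frame errors name the taxon before alignment checks
        if len(r.seq) % 3 != 0:
            raise AlignmentError(
                f"sequence length of taxon '{r.id}' ({len(r.seq)} nt) "
                f"is not divisible by 3")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise AlignmentError("sequences are not aligned (unequal lengths)")
    rows = [_encode_sequence(r.id, str(r.seq), code) for r in records]
    aln = CodonAlignment(names, np.vstack(rows), code)
    # drop a trailing all-stop/gap column introduced by CDS terminal stops
    if aln.n_codons > 1 and np.all(aln.codons[:, -1] == MISSING):
        last_codons = {str(r.seq[-3:]).upper() for r in records}
        if last_codons & set(code.stop_codons):
            aln = CodonAlignment(names, aln.codons[:, :-1], code,
                                 aln.site_index[:-1])
    return aln


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    records = [SeqRecord(Seq(s), id=t, description="")
               for t, s in aln.to_strings().items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class Phylogeny:
    """A phylogeny with named leaves and branch lengths in expected
    substitutions per codon."""

    tree: dendropy.Tree

    @property
    def leaf_names(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    def validate_lengths(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    def pair_with(self, aln: CodonAlignment) -> None:
        """Check leaf set equals alignment taxa; raise naming offenders."""
        leaves = set(self.leaf_names)
        taxa = set(aln.taxa)
        missing = sorted(leaves - taxa)
        extra = sorted(taxa - leaves)
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"tree leaves absent from alignment: {', '.join(missing)}")
            if extra:
                parts.append(f"alignment taxa absent from tree: {', '.join(extra)}")
            raise ValueError("; ".join(parts))

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path_or_string) -> Phylogeny:
    """Read a newick tree from a path or a literal newick string."""
    text = str(path_or_string)
    if text.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=text, schema="newick")
    else:
        tree = dendropy.Tree.get(path=text, schema="newick")
    phy = Phylogeny(tree)
    phy.validate_lengths()
    return phy


def write_newick(phy: Phylogeny, path) -> None:
    phy.tree.write(path=str(path), schema="newick", suppress_rooting=True)


@dataclass
class MaskSpec:
    """Closed 1-based codon intervals to exclude from analysis."""

    intervals: list

    def normalized(self) -> list:
        ivals = sorted((int(a), int(b)) for a, b in self.intervals)
        merged = []
        for a, b in ivals:
            if a > b:
                raise ValueError(f"interval [{a}, {b}] is reversed")
            if merged and a <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        return merged

    def covered(self, n_codons: int) -> np.ndarray:
        mask = np.zeros(n_codons, dtype=bool)
        for a, b in self.normalized():
            if a < 1 or b > n_codons:
                raise ValueError(
                    f"mask interval [{a}, {b}] outside [1, {n_codons}]")
            mask[a - 1:b] = True
        return mask


def mask_codon_range(aln: CodonAlignment, spec: MaskSpec) -> CodonAlignment:
    """Remove masked codon columns; retained columns keep gene numbering."""
    keep = np.ones(aln.n_codons, dtype=bool)
    for a, b in spec.normalized():
        if a < 1 or b > int(aln.site_index.max()):
            raise ValueError(f"mask interval [{a}, {b}] outside gene bounds")
        keep &= ~((aln.site_index >= a) & (aln.site_index <= b))
    if not keep.any():
        raise ValueError("mask covers every codon; empty alignment")
    return CodonAlignment(list(aln.taxa), aln.codons[:, keep], aln.code,
                          aln.site_index[keep])


@dataclass
class CodonFrequencies:
    """Equilibrium codon frequencies over the 61 sense codons."""

    scheme: str
    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.ndim != 1:
            raise ValueError("pi must be a vector")
        if not np.all(np.isfinite(self.pi)) or np.any(self.pi < 0):
            raise ValueError("pi must be finite and non-negative")
        s = self.pi.sum()
        if abs(s - 1.0) > 1e-8:
            raise ValueError(f"pi sums to {s}, not 1")


def equal_frequencies(code: GeneticCode = STANDARD_CODE) -> CodonFrequencies:
    n = code.n_sense
    return CodonFrequencies("equal", np.full(n, 1.0 / n))


def estimate_codon_frequencies(aln: CodonAlignment,
                               scheme: str = "F3X4") -> CodonFrequencies:
    """Estimate codon frequencies under ``equal``, ``F3X4``, or ``F61``.

    F3X4 multiplies position-specific nucleotide frequencies and renormalizes
    over sense codons; F61 uses empirical codon counts with a 0.5 pseudocount
    per codon (zero frequencies break reversibility scaling).
    """
    code = aln.code
    n = code.n_sense
    if aln.n_codons == 0 or not np.any(aln.codons >= 0):
        raise AlignmentError("empty alignment; cannot estimate frequencies")
    if scheme == "equal":
        return equal_frequencies(code)
    if scheme == "F61":
        counts = np.bincount(aln.codons[aln.codons >= 0], minlength=n).astype(float)
        counts += 0.5
        return CodonFrequencies("F61", counts / counts.sum())
    if scheme == "F3X4":
        nt_index = {b: i for i, b in enumerate(NUCLEOTIDES)}
        # 0.5 pseudocount per nucleotide keeps every sense codon reachable
        pos_counts = np.full((3, 4), 0.5)
        flat = aln.codons[aln.codons >= 0]
        for ci in flat:
            codon = code.sense_codons[ci]
            for p, b in enumerate(codon):
                pos_counts[p, nt_index[b]] += 1
        pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        pi = np.empty(n)
        for i, codon in enumerate(code.sense_codons):
            pi[i] = np.prod([pos_freq[p, nt_index[b]]
                             for p, b in enumerate(codon)])
        return CodonFrequencies("F3X4", pi / pi.sum())
    raise ValueError(f"unknown frequency scheme '{scheme}'")


def frequencies_to_tsv(freqs: CodonFrequencies, path,
                       code: GeneticCode = STANDARD_CODE) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tweight\n")
        for codon, w in zip(code.sense_codons, freqs.pi):
            fh.write(f"{codon}\t{w:.10g}\n")
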