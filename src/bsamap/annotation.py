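"""Codon-level variant-effect classification and gene-model annotation.

Single-nucleotide substitutions inside a coding sequence are classified by
translating the reference and alternate codons with the standard genetic
code (NCBI table 1 — plant nuclear genes): same amino acid is synonymous,
a new stop is stop_gained, a lost stop is stop_lost, a disrupted annotated
start codon is start_lost, anything else non-synonymous. Variants outside
any CDS are labelled non-coding.

Codon-change notation like "aTc/aGc" (the mutated base conventionally
upper-case) is parsed directly, so a published table of codon changes can be
re-classified without the genome. A bundled table carries the 16 SNPs found
in the promoter and coding region of the candidate male-sterility gene
(9 non-synonymous, 7 synonymous).
"""

from __future__ import annotations

from collections import Counter
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "classify_codon_change",
    "parse_codon_change",
    "collapse_effect",
    "count_effects",
    "load_candidate_gene_snps",
    "classify_table",
    "GeneModel",
    "load_gene_models",
    "annotate_variants",
    "nonsynonymous_gene_tally",
]

_DNA = set("ACGT")
_STOPS = set(standard_dna_table.stop_codons)

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non_synonymous"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"
NON_CODING = "non_coding"


def _translate(codon: str) -> str:
    return "*" if codon in _STOPS else standard_dna_table.forward_table[codon]


def classify_codon_change(ref_codon: str, alt_codon: str, is_start: bool = False) -> str:
    """Effect of a single-base codon substitution under the standard code.

    Case-insensitive. Codons must be length-3 DNA strings differing at
    exactly one position. ``is_start`` marks an annotated initiation codon,
    enabling the start_lost call.
    """
    ref = ref_codon.upper()
    alt = alt_codon.upper()
    for name, codon in (("reference", ref), ("alternate", alt)):
        if len(codon) != 3:
            raise ValueError(f"{name} codon must be length 3, got {codon!r}")
        if not set(codon) <= _DNA:
            raise ValueError(f"{name} codon has non-DNA characters: {codon!r}")
    n_diff = sum(a != b for a, b in zip(ref, alt))
    if n_diff != 1:
        raise ValueError(f"codons must differ at exactly one position, differ at {n_diff}")
    if is_start and ref == "ATG" and alt != "ATG":
        return START_LOST
    ref_stop, alt_stop = ref in _STOPS, alt in _STOPS
    if ref_stop and alt_stop:
        return SYNONYMOUS
    if alt_stop:
        return STOP_GAINED
    if ref_stop:
        return STOP_LOST
    return SYNONYMOUS if _translate(ref) == _translate(alt) else NON_SYNONYMOUS


def parse_codon_change(notation: str) -> tuple[str, str, int]:
    """Parse "aTc/aGc"-style notation to (ref_codon, alt_codon, mutated_index).

    The mutated position is taken from the upper-case letter; if the case is
    uniform across the codon the position falls back to the single differing
    base.
    """
    try:
        ref, alt = notation.strip().split("/")
    except ValueError as exc:
        raise ValueError(f"codon change must be 'ref/alt', got {notation!r}") from exc
    if len(ref) != 3 or len(alt) != 3:
        raise ValueError(f"codons must be length 3 in {notation!r}")
    upper = [i for i in range(3) if ref[i].isupper() or alt[i].isupper()]
    if len(upper) == 1:
        idx = upper[0]
    else:
        diff = [i for i in range(3) if ref[i].upper() != alt[i].upper()]
        if len(diff) != 1:
            raise ValueError(f"cannot locate the mutated base in {notation!r}")
        idx = diff[0]
    return ref, alt, idx


def collapse_effect(effect: str) -> str:
    """Two-label collapse: every coding change that is not synonymous counts
    as non-synonymous (matching published BSA summaries)."""
    if effect in (SYNONYMOUS, NON_CODING):
        return effect
    return NON_SYNONYMOUS


def count_effects(effects) -> tuple[int, int, int]:
    """(n_synonymous, n_non_synonymous, n_other) tallies over effect labels.

    With ``collapse_effect`` applied upstream, ``n_other`` counts only
    non-coding labels.
    """
    counts = Counter(effects)
    n_syn = counts.pop(SYNONYMOUS, 0)
    n_nonsyn = counts.pop(NON_SYNONYMOUS, 0)
    return n_syn, n_nonsyn, sum(counts.values())


def load_candidate_gene_snps() -> pd.DataFrame:
    """The bundled codon-change table for the candidate male-sterility gene."""
    with resources.files("bsamap.data").joinpath("candidate_gene_snps.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def classify_table(table: pd.DataFrame, collapse: bool = True) -> pd.DataFrame:
    """Classify a codon-change table (column ``codon_change``); adds
    ``effect_called`` labels ("Synonymous coding"/"Non-synonymous coding"
    when collapsed, to compare against published labels) and ``effect_raw``."""
    raw, called = [], []
    for notation in table["codon_change"]:
        ref, alt, _ = parse_codon_change(notation)
        effect = classify_codon_change(ref, alt)
        raw.append(effect)
        label = collapse_effect(effect) if collapse else effect
        called.append(
            "Synonymous coding" if label == SYNONYMOUS else "Non-synonymous coding"
        )
    out = table.copy()
    out["effect_raw"] = raw
    out["effect_called"] = called
    return out


class GeneModel:
    """A protein-coding gene: strand-aware ordered CDS intervals.

    ``cds`` is a list of (start, end) 1-based inclusive genomic intervals in
    genomic order; a total CDS length not divisible by 3 is flagged, not
    fatal (the trailing partial codon is ignored).
    """

    def __init__(self, gene_id: str, chrom: str, strand: str, cds: list[tuple[int, int]]):
        if strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        cds = sorted(cds)
        for (a, b), (c, d) in zip(cds, cds[1:]):
            if c <= b:
                raise ValueError(f"{gene_id}: overlapping CDS intervals")
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.cds = cds
        self.length = sum(b - a + 1 for a, b in cds)
        self.frame_ok = self.length % 3 == 0

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS,
        counted from the start codon, or None if outside every interval."""
        off = 0
        for a, b in self.cds:
            if a <= pos <= b:
                genomic = off + (pos - a)
                return genomic if self.strand == "+" else self.length - 1 - genomic
            off += b - a + 1
        return None

    def cds_sequence(self, fasta) -> str:
        """Spliced coding sequence 5'->3' from an indexed FASTA."""
        parts = [str(fasta[self.chrom][a - 1 : b]) for a, b in self.cds]
        seq = "".join(parts).upper()
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def load_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Read protein-coding gene models (CDS features grouped by parent) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        cds = [
            (c.start, c.end)
            for c in db.children(gene, featuretype="CDS", order_by="start")
        ]
        if cds:
            models.append(GeneModel(gene.id, gene.seqid, gene.strand, cds))
    return models


def annotate_variants(
    variants: pd.DataFrame,
    gene_models: list[GeneModel],
    fasta,
) -> pd.DataFrame:
    """Codon-level effect per variant against supplied gene models.

    ``variants`` needs chrom, pos, ref, alt columns (SNVs, plus-strand
    alleles as in VCF); ``fasta`` is a ``pyfaidx.Fasta``-like mapping.
    Adds ``gene_id``, ``effect``, ``ref_codon``, ``alt_codon`` columns;
    variants outside every CDS get effect ``non_coding``. A reference allele
    that contradicts the FASTA raises.
    """
    comp = str.maketrans("ACGT", "TGCA")
    out_gene, out_eff, out_rc, out_ac = [], [], [], []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for row in variants.itertuples(index=False):
        hit = None
        for g in by_chrom.get(row.chrom, ()):
            off = g.cds_offset(row.pos)
            if off is not None:
                hit = (g, off)
                break
        if hit is None:
            out_gene.append("")
            out_eff.append(NON_CODING)
            out_rc.append("")
            out_ac.append("")
            continue
        g, off = hit
        cds = g.cds_sequence(fasta)
        ref_base = str(fasta[row.chrom][row.pos - 1]).upper()
        if ref_base != row.ref.upper():
            raise ValueError(
                f"reference mismatch at {row.chrom}:{row.pos}: "
                f"FASTA has {ref_base}, variant claims {row.ref}"
            )
        codon_i = off // 3
        if 3 * codon_i + 3 > len(cds):
            out_gene.append(g.gene_id)
            out_eff.append(NON_CODING)  # trailing partial codon of a flagged model
            out_rc.append("")
            out_ac.append("")
            continue
        within = off % 3
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        alt_base = row.alt.upper()
        if g.strand == "-":
            alt_base = alt_base.translate(comp)
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        out_gene.append(g.gene_id)
        out_eff.append(classify_codon_change(ref_codon, alt_codon, is_start=codon_i == 0 and ref_codon == "ATG"))
        out_rc.append(ref_codon)
        out_ac.append(alt_codon)
    out = variants.copy()
    out["gene_id"] = out_gene
    out["effect"] = out_eff
    out["ref_codon"] = out_rc
    out["alt_codon"] = out_ac
    return out


def nonsynonymous_gene_tally(annotated: pd.DataFrame) -> pd.Series:
    """Per-gene count of (collapsed) non-synonymous variants, descending."""
    coding = annotated[annotated["gene_id"] != ""]
    nonsyn = coding[coding["effect"].map(collapse_effect) == NON_SYNONYMOUS]
    return nonsyn.groupby("gene_id").size().sort_values(ascending=False)
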