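"""Screen ORFs for luxI/luxR homologs and audit their conserved residues.

An ORF is called a putative quorum-sensing gene when its best bitscore
against a QS-related KEGG orthology (AHL synthase K13060/K13061/K13062/
K18096, AHL receptor K07782/K18098/K18099) strictly exceeds its best
bitscore against any other KO. Calls are independently validated against
conserved Pfam domains (autoinducer synthase Pfam00765 for LuxI;
autoinducer-binding Pfam03472 plus GerE Pfam00196 for LuxR), receptor
proteins are audited for the residues required for acyl binding
(W66, D79, P80, W94, G121) and DNA binding (E187, L191, G197) in reference
numbering, and synthase/receptor genes co-localized on a contig are
resolved into cognate pairs versus luxR "solos".
"""

from __future__ import annotations

import functools
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import DomainHit, HitRecord, OrfRecord

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: reference-numbering residues required for AHL (acyl) binding
ACYL_BINDING_POSITIONS: dict[int, str] = {66: "W", 79: "D", 80: "P", 94: "W", 121: "G"}
#: reference-numbering residues required for DNA binding
DNA_BINDING_POSITIONS: dict[int, str] = {187: "E", 191: "L", 197: "G"}

PFAM_AHL_SYNTHASE = "Pfam00765"
PFAM_AUTOINDUCER_BINDING = "Pfam03472"
PFAM_GERE = "Pfam00196"


@dataclass(frozen=True)
class QsKoSets:
    synthase_kos: frozenset[str] = frozenset(
        {"K13060", "K13061", "K13062", "K18096"}
    )
    receptor_kos: frozenset[str] = frozenset({"K07782", "K18098", "K18099"})

    def __post_init__(self) -> None:
        if not self.synthase_kos or not self.receptor_kos:
            raise ValueError("KO sets must be non-empty")
        if self.synthase_kos & self.receptor_kos:
            raise ValueError("synthase and receptor KO sets must be disjoint")

    @property
    def all_qs(self) -> frozenset[str]:
        return self.synthase_kos | self.receptor_kos


@dataclass(frozen=True)
class QsCandidate:
    orf_id: str
    role: str  # "synthase" | "receptor"
    best_qs_ko: str
    best_qs_score: float
    best_other_score: Optional[float] = None
    domain_validated: Optional[bool] = None  # None = untested

    def __post_init__(self) -> None:
        if self.best_other_score is not None:
            if not self.best_qs_score > self.best_other_score:
                raise ValueError(
                    f"{self.orf_id}: QS score must strictly exceed other score"
                )


@dataclass(frozen=True)
class ResidueCheck:
    reference_position: int
    expected: str
    observed: Optional[str]  # None = aligned to a gap
    conserved: bool


@dataclass(frozen=True)
class ConservationReport:
    orf_id: str
    acyl_binding: tuple[ResidueCheck, ...]
    dna_binding: tuple[ResidueCheck, ...]
    missense_acyl: int = field(init=False, default=0)
    missense_dna: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "missense_acyl",
            sum(1 for c in self.acyl_binding if c.observed is not None and not c.conserved),
        )
        object.__setattr__(
            self,
            "missense_dna",
            sum(1 for c in self.dna_binding if c.observed is not None and not c.conserved),
        )


@dataclass(frozen=True)
class LuxPair:
    synthase_id: str
    receptor_id: str
    intervening_orf_count: int
    orientation: str  # divergent | convergent | tandem


@dataclass(frozen=True)
class LuxPairing:
    pairs: tuple[LuxPair, ...]
    solo_receptors: tuple[str, ...]
    unpaired_synthases: tuple[str, ...]


# ---------------------------------------------------------------------------
# KO best-hit classification
# ---------------------------------------------------------------------------


def classify_qs_orfs(
    hits: Iterable[HitRecord], ko_sets: QsKoSets = QsKoSets()
) -> list[QsCandidate]:
    """Call putative QS genes by the KO best-hit rule.

    An ORF qualifies iff its maximum bitscore among QS-KO hits strictly
    exceeds its maximum bitscore among non-QS-KO hits (hits without a KO
    label do not compete). Ties are rejected and logged. Output is sorted
    by orf_id; the rule is invariant under row permutation/duplication.
    """
    grouped: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        grouped[h.orf_id].append(h)
    out: list[QsCandidate] = []
    for orf_id in sorted(grouped):
        qs_hits = [h for h in grouped[orf_id] if h.ko_id in ko_sets.all_qs]
        other = [
            h
            for h in grouped[orf_id]
            if h.ko_id is not None and h.ko_id not in ko_sets.all_qs
        ]
        if not qs_hits:
            continue
        best_qs = max(qs_hits, key=lambda h: (h.bitscore, h.ko_id))
        best_other = max((h.bitscore for h in other), default=None)
        if best_other is not None:
            if best_qs.bitscore == best_other:
                logger.warning(
                    "ORF %s: best QS score ties best non-QS score (%.3g); "
                    "rejected under the strict rule",
                    orf_id,
                    best_other,
                )
                continue
            if best_qs.bitscore < best_other:
                continue
        role = "synthase" if best_qs.ko_id in ko_sets.synthase_kos else "receptor"
        out.append(
            QsCandidate(
                orf_id=orf_id,
                role=role,
                best_qs_ko=best_qs.ko_id,  # type: ignore[arg-type]
                best_qs_score=best_qs.bitscore,
                best_other_score=best_other,
            )
        )
    return out


def _pfam_key(accession: str) -> str:
    """Normalize 'Pfam00765' / 'PF00765' / 'PF00765.29' to the numeric part."""
    digits = "".join(ch for ch in accession.split(".")[0] if ch.isdigit())
    return digits.lstrip("0") or "0"


def validate_domains(
    candidates: Sequence[QsCandidate],
    domain_hits: Iterable[DomainHit],
    evalue_max: float = 1e-5,
) -> list[QsCandidate]:
    """Set domain_validated from a precomputed Pfam hit table.

    Synthases need the autoinducer synthase domain; receptors need both the
    autoinducer-binding and the GerE (DNA-binding) domains. An empty table
    leaves every candidate untested (None).
    """
    hits = list(domain_hits)
    if not hits:
        return [replace(c, domain_validated=None) for c in candidates]
    known = {c.orf_id for c in candidates}
    per_orf: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.orf_id not in known:
            logger.warning("domain hit for unknown ORF %s ignored", h.orf_id)
            continue
        if h.evalue <= evalue_max:
            per_orf[h.orf_id].add(_pfam_key(h.domain_id))
    syn_key = _pfam_key(PFAM_AHL_SYNTHASE)
    rec_keys = {_pfam_key(PFAM_AUTOINDUCER_BINDING), _pfam_key(PFAM_GERE)}
    out = []
    for c in candidates:
        found = per_orf.get(c.orf_id, set())
        ok = syn_key in found if c.role == "synthase" else rec_keys <= found
        out.append(replace(c, domain_validated=ok))
    return out


# ---------------------------------------------------------------------------
# global alignment and residue audit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlobalAlignment:
    score: float
    #: 1-based reference position -> aligned query residue, or None for a gap
    ref_to_query: Mapping[int, Optional[str]]


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # NCBI convention: a length-k gap costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_global(
    query: str,
    reference: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    matrix: str = "BLOSUM62",
) -> GlobalAlignment:
    """Optimal global protein alignment with a reference-position map."""
    for name, seq in (("query", query), ("reference", reference)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq) - STANDARD_AA
        if bad:
            raise ValueError(f"{name} contains non-standard residues {sorted(bad)}")
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(reference, query)[0]
    ref_to_query: dict[int, Optional[str]] = {i: None for i in range(1, len(reference) + 1)}
    ref_blocks, query_blocks = aln.aligned
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        for k in range(re_ - rs):
            ref_to_query[rs + k + 1] = query[qs + k]
    return GlobalAlignment(score=float(aln.score), ref_to_query=ref_to_query)


@functools.lru_cache(maxsize=1)
def default_luxr_reference(length: int = 210, seed: int = 20210) -> str:
    """Synthetic 210-aa reference LuxR with the audited residues planted.

    This is a stand-in numbering scaffold, not a real LuxR sequence: the
    background residues are drawn deterministically and the eight audited
    positions carry their expected residues. Supply your own reference to
    audit against a biological numbering scheme.
    """
    rng = np.random.default_rng(seed)
    alphabet = sorted(STANDARD_AA)
    residues = [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]
    for pos, aa in {**ACYL_BINDING_POSITIONS, **DNA_BINDING_POSITIONS}.items():
        residues[pos - 1] = aa
    return "".join(residues)


def check_luxr_conservation(
    query: str,
    reference: Optional[str] = None,
    acyl_positions: Mapping[int, str] = ACYL_BINDING_POSITIONS,
    dna_positions: Mapping[int, str] = DNA_BINDING_POSITIONS,
    orf_id: str = "",
    **align_kwargs,
) -> ConservationReport:
    """Audit a candidate LuxR for the conserved acyl- and DNA-binding residues.

    The query is globally aligned to the reference; each annotated reference
    position reports the aligned query residue and whether it matches the
    expected residue exactly. Gaps are reported but not counted as missense.
    """
    reference = reference if reference is not None else default_luxr_reference()
    for pos, aa in {**acyl_positions, **dna_positions}.items():
        if pos > len(reference) or reference[pos - 1] != aa:
            raise ValueError(
                f"reference lacks expected residue {aa} at position {pos} "
                f"(found {reference[pos - 1] if pos <= len(reference) else 'end'})"
            )
    aln = align_global(query, reference, **align_kwargs)

    def audit(positions: Mapping[int, str]) -> tuple[ResidueCheck, ...]:
        checks = []
        for pos in sorted(positions):
            observed = aln.ref_to_query[pos]
            checks.append(
                ResidueCheck(
                    reference_position=pos,
                    expected=positions[pos],
                    observed=observed,
                    conserved=observed == positions[pos],
                )
            )
        return tuple(checks)

    return ConservationReport(
        orf_id=orf_id,
        acyl_binding=audit(acyl_positions),
        dna_binding=audit(dna_positions),
    )


# ---------------------------------------------------------------------------
# cognate pairing
# ---------------------------------------------------------------------------


def _orientation(left: OrfRecord, right: OrfRecord) -> str:
    if left.strand == right.strand:
        return "tandem"
    # facing away from each other (promoters in the shared gap)
    return "divergent" if left.strand == "-" else "convergent"


def pair_lux_genes(
    candidates: Sequence[QsCandidate],
    orfs: Sequence[OrfRecord],
    max_intervening: int = 3,
) -> LuxPairing:
    """Resolve cognate luxI/luxR pairs by contig co-localization.

    A synthase and a receptor on the same contig separated by at most
    ``max_intervening`` ORFs (in contig order of start positions) may pair;
    nearest pairs are matched first (greedy), each gene in at most one pair.
    Receptors left over are luxR solos; synthases left over are unpaired.
    """
    by_id = {o.id: o for o in orfs}
    order: dict[str, int] = {}
    per_contig: dict[str, list[OrfRecord]] = defaultdict(list)
    for o in orfs:
        per_contig[o.contig_id].append(o)
    for contig_orfs in per_contig.values():
        for idx, o in enumerate(sorted(contig_orfs, key=lambda x: (x.start, x.id))):
            order[o.id] = idx

    synthases = sorted(c.orf_id for c in candidates if c.role == "synthase")
    receptors = sorted(c.orf_id for c in candidates if c.role == "receptor")
    for orf_id in synthases + receptors:
        if orf_id not in by_id:
            raise ValueError(f"candidate {orf_id!r} references an unknown ORF")

    proposals: list[tuple[int, str, str]] = []
    for s in synthases:
        for r in receptors:
            so, ro = by_id[s], by_id[r]
            if so.contig_id != ro.contig_id:
                continue
            intervening = abs(order[s] - order[r]) - 1
            if 0 <= intervening <= max_intervening:
                proposals.append((intervening, s, r))
    proposals.sort()

    taken: set[str] = set()
    pairs: list[LuxPair] = []
    for intervening, s, r in proposals:
        if s in taken or r in taken:
            continue
        taken.update((s, r))
        so, ro = by_id[s], by_id[r]
        left, right = (so, ro) if so.start <= ro.start else (ro, so)
        pairs.append(
            LuxPair(
                synthase_id=s,
                receptor_id=r,
                intervening_orf_count=intervening,
                orientation=_orientation(left, right),
            )
        )
    return LuxPairing(
        pairs=tuple(pairs),
        solo_receptors=tuple(r for r in receptors if r not in taken),
        unpaired_synthases=tuple(s for s in synthases if s not in taken),
    )
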