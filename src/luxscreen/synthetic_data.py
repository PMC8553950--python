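"""Seeded synthetic communities with planted quorum-sensing ground truth.

The generator emits exactly the inputs the screen consumes — contigs
(FASTA), ORF calls (GFF3), KO/taxonomy-annotated hit tables (TSV), Pfam
domain tables (TSV), receptor protein sequences (FASTA) — plus a truth
manifest (JSON) sufficient to score recovery of every planted element:
luxI/luxR roles, cognate pairs and solos, contig lineages, and lux boxes
inserted at exact distances upstream of their target genes.

Defaults emulate the study conditions at desk scale: 13 synthases of which
9 are paired with receptors, 21 receptor solos, a 54-site lux-box library
mutated at 5% per column from the consensus ACCTGGCGGTTCCGCCAGGT, and one
cognate pair on a Nitrospira-lineage contig with the box planted 81 bp
upstream of the synthase and 125 bp upstream of the divergently
transcribed partner gene.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    Contig,
    DomainHit,
    HitRecord,
    MotifLibrary,
    OrfRecord,
    TaxonomyPath,
    write_domain_table,
    write_fasta,
    write_hit_table,
    write_orfs_gff,
)
from .luxbox import UpstreamRegion, palindrome_mismatches
from .qs_gene_screen import (
    ACYL_BINDING_POSITIONS,
    PFAM_AHL_SYNTHASE,
    PFAM_AUTOINDUCER_BINDING,
    PFAM_GERE,
    STANDARD_AA,
    default_luxr_reference,
)

#: the common lux box bound bidirectionally by the Nitrospira LuxR
DEFAULT_CONSENSUS = "ACCTGGCGGTTCCGCCAGGT"

DEFAULT_TAXA: tuple[tuple[str, float], ...] = (
    ("superkingdom:Bacteria;phylum:Proteobacteria;class:Alphaproteobacteria", 0.15),
    ("superkingdom:Bacteria;phylum:Proteobacteria;class:Betaproteobacteria", 0.24),
    ("superkingdom:Bacteria;phylum:Proteobacteria;class:Gammaproteobacteria", 0.16),
    ("superkingdom:Bacteria;phylum:Proteobacteria;class:Deltaproteobacteria", 0.19),
    ("superkingdom:Bacteria;phylum:Nitrospirae;genus:Nitrospira", 0.10),
    ("superkingdom:Bacteria;phylum:Bacteroidetes", 0.10),
    ("superkingdom:Bacteria;phylum:Chloroflexi", 0.06),
)

SYNTHASE_FUNCTION = "acyl-homoserine-lactone synthase"
RECEPTOR_FUNCTION = "LuxR-family transcriptional regulator"

_DECOY_KOS = ("K00001", "K00370", "K01915", "K02335", "K03531", "K10944")


@dataclass(frozen=True)
class LuxBoxPlant:
    """Plant one lux box upstream of the pair_index-th cognate synthase."""

    pair_index: int
    distance_upstream: int = 81  # to the synthase start codon
    partner_distance: int = 125  # to the divergent partner's start codon
    n_mutations: int = 0

    def __post_init__(self) -> None:
        for d in (self.distance_upstream, self.partner_distance):
            if not (0 <= d <= 380):
                raise ValueError("box distance must be in [0, 380]")


@dataclass(frozen=True)
class CommunityConfig:
    seed: int
    n_contigs: int = 40
    contig_length: tuple[int, int] = (2000, 20000)
    orf_density: float = 0.9  # ORFs per kb on background contigs
    gc_content: float = 0.5
    taxa: tuple[tuple[str, float], ...] = DEFAULT_TAXA
    n_luxI: int = 13
    n_luxR_paired: int = 9
    n_luxR_solo: int = 21
    luxbox_plants: Optional[tuple[LuxBoxPlant, ...]] = None  # None -> one per pair
    motif_consensus: str = DEFAULT_CONSENSUS
    library_size: int = 54
    library_mutation_rate: float = 0.05
    solo_missense_range: tuple[int, int] = (1, 3)
    lineage_noise: float = 0.12  # fraction of filler ORFs with off-lineage hits
    target_taxon: tuple[str, str] = ("genus", "Nitrospira")

    def __post_init__(self) -> None:
        if any(w <= 0 for _, w in self.taxa):
            raise ValueError("taxa weights must be positive")
        if not (0 <= self.library_mutation_rate <= 0.5):
            raise ValueError("library mutation rate must be in [0, 0.5]")

    def config_hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class SyntheticTruth:
    seed: int
    config_hash: str
    roles: dict[str, str]  # orf_id -> synthase | receptor | decoy
    orf_lineages: dict[str, str]
    contig_lineages: dict[str, str]
    pairs: list[tuple[str, str]]  # (synthase, receptor)
    solo_receptors: list[str]
    unpaired_synthases: list[str]
    boxes: list[dict]
    receptor_missense: dict[str, dict[int, str]]
    counts: dict[str, int]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["receptor_missense"] = {
            orf: {str(p): aa for p, aa in subs.items()}
            for orf, subs in self.receptor_missense.items()
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticCommunity:
    contigs: list[Contig]
    orfs: list[OrfRecord]
    hits: list[HitRecord]
    domain_hits: list[DomainHit]
    proteins: dict[str, str]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": outdir / "community.fasta",
            "orfs": outdir / "orfs.gff3",
            "hits": outdir / "hits.tsv",
            "domains": outdir / "domains.tsv",
            "proteins": outdir / "proteins.faa",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.contigs, paths["contigs"])
        write_orfs_gff(self.orfs, paths["orfs"])
        write_hit_table(self.hits, paths["hits"])
        write_domain_table(self.domain_hits, paths["domains"])
        with open(paths["proteins"], "w") as fh:
            for orf_id in sorted(self.proteins):
                fh.write(f">{orf_id}\n{self.proteins[orf_id]}\n")
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------


def _mutate(site: str, rng: np.random.Generator, rate: float) -> str:
    bases = "ACGT"
    out = list(site)
    for i, b in enumerate(out):
        if rng.random() < rate:
            alternatives = [x for x in bases if x != b]
            out[i] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def _mutate_k(site: str, rng: np.random.Generator, k: int) -> str:
    """Substitute exactly k distinct positions."""
    bases = "ACGT"
    out = list(site)
    for i in rng.choice(len(site), size=k, replace=False):
        alternatives = [x for x in bases if x != out[i]]
        out[i] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def generate_motif_library(
    consensus: str = DEFAULT_CONSENSUS,
    n: int = 54,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> MotifLibrary:
    """Draw n aligned sites by per-position mutation of a consensus.

    Stands in for a curated library of experimentally reported lux boxes;
    the consensus must itself be an imperfect palindrome (<= 8 mismatching
    positions against its reverse complement).
    """
    if not (0 <= mutation_rate <= 0.5):
        raise ValueError("mutation_rate must be in [0, 0.5]")
    if palindrome_mismatches(consensus) > 8:
        raise ValueError("consensus is not an imperfect palindrome")
    rng = np.random.default_rng(seed)
    sites = tuple(_mutate(consensus, rng, mutation_rate) for _ in range(n))
    ids = tuple(f"site{i + 1:02d}" for i in range(n))
    return MotifLibrary(ids=ids, sites=sites)


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


class _ContigBuilder:
    def __init__(self, cid: str, rng: np.random.Generator):
        self.cid = cid
        self.rng = rng
        self.pos = 1  # next free 1-based coordinate
        self.orfs: list[tuple[int, int, str]] = []  # (start, end, strand)

    def gap(self, n: int) -> None:
        self.pos += n

    def orf(self, length: int, strand: str) -> tuple[int, int]:
        start, end = self.pos, self.pos + length - 1
        self.orfs.append((start, end, strand))
        self.pos = end + 1
        return start, end


def _pick_lineage(rng: np.random.Generator, taxa: Sequence[tuple[str, float]]) -> str:
    weights = np.array([w for _, w in taxa], float)
    return taxa[rng.choice(len(taxa), p=weights / weights.sum())][0]


def _off_lineage(rng, taxa, lineage: str) -> str:
    others = [t for t in taxa if t[0] != lineage]
    return _pick_lineage(rng, others) if others else lineage


def generate_community(config: CommunityConfig) -> SyntheticCommunity:
    """Generate a full cross-consistent synthetic community.

    Deterministic under (config, seed): one root seed spawns per-component
    child streams (sequences, placement, hits, proteins, boxes).
    """
    root = np.random.default_rng(config.seed)
    seq_rng, place_rng, hit_rng, prot_rng, box_rng = root.spawn(5)

    n_pairs = min(config.n_luxI, config.n_luxR_paired)
    n_lone_syn = config.n_luxI - n_pairs
    n_background = config.n_contigs - n_pairs
    if n_background < n_lone_syn + config.n_luxR_solo:
        raise ValueError(
            "infeasible config: need at least one background contig per "
            "unpaired synthase and solo receptor"
        )
    plants = config.luxbox_plants
    if plants is None:
        plants = tuple(LuxBoxPlant(pair_index=i) for i in range(n_pairs))
    if any(p.pair_index >= n_pairs for p in plants):
        raise ValueError("luxbox plant references a non-existent pair")
    plant_by_pair = {p.pair_index: p for p in plants}

    target_lineages = [
        lin for lin, _ in config.taxa
        if f"{config.target_taxon[0]}:{config.target_taxon[1]}" in lin
    ]

    contigs: list[Contig] = []
    orfs: list[OrfRecord] = []
    roles: dict[str, str] = {}
    orf_lineage: dict[str, str] = {}
    contig_lineage: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    boxes: list[dict] = []
    receptor_missense: dict[str, dict[int, str]] = {}
    proteins: dict[str, str] = {}

    def orf_id(cid: str, idx: int) -> str:
        return f"{cid}_orf{idx:03d}"

    # --- cognate-pair contigs -------------------------------------------
    for pair_i in range(n_pairs):
        cid = f"pair{pair_i + 1:02d}"
        if pair_i == 0 and target_lineages:
            lineage = target_lineages[0]
        else:
            lineage = _pick_lineage(place_rng, config.taxa)
        contig_lineage[cid] = lineage
        b = _ContigBuilder(cid, place_rng)
        plant = plant_by_pair.get(pair_i)
        d_syn = plant.distance_upstream if plant else 81
        d_rec = plant.partner_distance if plant else 125
        width = len(config.motif_consensus)

        b.gap(int(place_rng.integers(250, 400)))
        for _ in range(4):
            b.orf(int(place_rng.integers(400, 800)), "+-"[place_rng.integers(0, 2)])
            b.gap(int(place_rng.integers(150, 300)))
        rec_coords = b.orf(int(place_rng.integers(500, 700)), "-")
        b.gap(d_rec + width + d_syn)  # divergent promoter gap holding the box
        syn_coords = b.orf(int(place_rng.integers(500, 700)), "+")
        for _ in range(4):
            b.gap(int(place_rng.integers(150, 300)))
            b.orf(int(place_rng.integers(400, 800)), "+-"[place_rng.integers(0, 2)])
        b.gap(int(place_rng.integers(250, 400)))

        length = b.pos - 1
        seq = list(_random_dna(seq_rng, length, config.gc_content))
        syn_start = syn_coords[0]
        if plant is not None:
            site = _mutate_k(config.motif_consensus, box_rng, plant.n_mutations)
            g1 = syn_start - d_syn - width
            g2 = syn_start - d_syn - 1
            seq[g1 - 1 : g2] = list(site)
        contigs.append(Contig(id=cid, sequence="".join(seq)))

        syn_id = rec_id = None
        for idx, (start, end, strand) in enumerate(b.orfs):
            oid = orf_id(cid, idx)
            orfs.append(OrfRecord(id=oid, contig_id=cid, start=start, end=end, strand=strand))
            if (start, end) == syn_coords:
                roles[oid], syn_id = "synthase", oid
            elif (start, end) == rec_coords:
                roles[oid], rec_id = "receptor", oid
            else:
                roles[oid] = "decoy"
            orf_lineage[oid] = lineage
        assert syn_id and rec_id
        pairs.append((syn_id, rec_id))
        receptor_missense[rec_id] = {}
        proteins[rec_id] = default_luxr_reference()
        if plant is not None:
            boxes.append(
                {
                    "contig_id": cid,
                    "genomic_start": g1,
                    "genomic_end": g2,
                    "site": site,
                    "distance_upstream": d_syn,
                    "partner_distance": d_rec,
                    "target_orfs": [syn_id, rec_id],
                    "n_mutations": plant.n_mutations,
                }
            )

    # --- background contigs ---------------------------------------------
    period = 1000.0 / config.orf_density
    mean_orf = 650.0
    gap_mean = period - mean_orf
    if gap_mean < 120:
        raise ValueError("infeasible config: ORF density too high for placement")
    background_ids = []
    for i in range(n_background):
        cid = f"ctg{i + 1:04d}"
        background_ids.append(cid)
        lineage = _pick_lineage(place_rng, config.taxa)
        contig_lineage[cid] = lineage
        length = int(place_rng.integers(config.contig_length[0], config.contig_length[1] + 1))
        b = _ContigBuilder(cid, place_rng)
        b.gap(int(place_rng.integers(150, 400)))
        while True:
            orf_len = int(place_rng.integers(400, 900))
            if b.pos + orf_len + 100 > length:
                break
            b.orf(orf_len, "+-"[place_rng.integers(0, 2)])
            b.gap(int(place_rng.integers(int(0.5 * gap_mean), int(1.5 * gap_mean))))
        contigs.append(Contig(id=cid, sequence=_random_dna(seq_rng, length, config.gc_content)))
        for idx, (start, end, strand) in enumerate(b.orfs):
            oid = orf_id(cid, idx)
            orfs.append(OrfRecord(id=oid, contig_id=cid, start=start, end=end, strand=strand))
            roles[oid] = "decoy"
            if place_rng.random() < config.lineage_noise:
                orf_lineage[oid] = _off_lineage(place_rng, config.taxa, lineage)
            else:
                orf_lineage[oid] = lineage

    # --- lone synthases and solo receptors on distinct background contigs
    host_ids = list(place_rng.permutation(background_ids))
    solo_receptors: list[str] = []
    unpaired_synthases: list[str] = []
    per_contig_orfs: dict[str, list[OrfRecord]] = {}
    for o in orfs:
        per_contig_orfs.setdefault(o.contig_id, []).append(o)

    def convert_middle_orf(cid: str, role: str) -> Optional[str]:
        candidates = [o for o in per_contig_orfs[cid] if roles[o.id] == "decoy"]
        if not candidates:
            return None
        chosen = candidates[len(candidates) // 2]
        roles[chosen.id] = role
        orf_lineage[chosen.id] = contig_lineage[cid]
        return chosen.id

    cursor = 0
    for _ in range(n_lone_syn):
        oid = None
        while oid is None and cursor < len(host_ids):
            oid = convert_middle_orf(host_ids[cursor], "synthase")
            cursor += 1
        if oid is None:
            raise ValueError("infeasible config: not enough host ORFs for synthases")
        unpaired_synthases.append(oid)
    for _ in range(config.n_luxR_solo):
        oid = None
        while oid is None and cursor < len(host_ids):
            oid = convert_middle_orf(host_ids[cursor], "receptor")
            cursor += 1
        if oid is None:
            raise ValueError("infeasible config: not enough host ORFs for solos")
        solo_receptors.append(oid)
        lo, hi = config.solo_missense_range
        k = int(prot_rng.integers(lo, hi + 1))
        positions = prot_rng.choice(sorted(ACYL_BINDING_POSITIONS), size=k, replace=False)
        ref = list(default_luxr_reference())
        subs: dict[int, str] = {}
        aa_pool = sorted(STANDARD_AA)
        for pos in sorted(int(p) for p in positions):
            current = ref[pos - 1]
            choices = [a for a in aa_pool if a != current]
            new_aa = choices[prot_rng.integers(0, len(choices))]
            ref[pos - 1] = new_aa
            subs[pos] = new_aa
        receptor_missense[oid] = subs
        proteins[oid] = "".join(ref)

    # --- hit and domain tables ------------------------------------------
    hits: list[HitRecord] = []
    domain_hits: list[DomainHit] = []
    for o in orfs:
        role = roles[o.id]
        lineage = TaxonomyPath.from_string(orf_lineage[o.id])
        if role == "decoy":
            b = float(hit_rng.uniform(80, 200))
            label = f"protein_family_{int(hit_rng.integers(0, 50)):02d}"
            other_label = f"protein_family_{int(hit_rng.integers(50, 99)):02d}"
            off = TaxonomyPath.from_string(
                _off_lineage(hit_rng, config.taxa, orf_lineage[o.id])
            )
            decoy_ko = _DECOY_KOS[int(hit_rng.integers(0, len(_DECOY_KOS)))]
            hits.append(HitRecord(o.id, f"nr|{o.id}_1", round(b, 1), decoy_ko, label, lineage))
            hits.append(
                HitRecord(o.id, f"nr|{o.id}_2", round(b * float(hit_rng.uniform(0.96, 0.99)), 1),
                          None, label, lineage)
            )
            hits.append(
                HitRecord(o.id, f"nr|{o.id}_3", round(b * float(hit_rng.uniform(0.70, 0.90)), 1),
                          None, other_label, off)
            )
        else:
            qs_ko = "K13060" if role == "synthase" else "K07782"
            func = SYNTHASE_FUNCTION if role == "synthase" else RECEPTOR_FUNCTION
            b = float(hit_rng.uniform(140, 180))
            decoy_ko = _DECOY_KOS[int(hit_rng.integers(0, len(_DECOY_KOS)))]
            hits.append(HitRecord(o.id, f"ko|{qs_ko}", round(b, 1), qs_ko, func, lineage))
            hits.append(
                HitRecord(o.id, f"ko|{decoy_ko}", round(b * float(hit_rng.uniform(0.60, 0.85)), 1),
                          decoy_ko, func, lineage)
            )
            hits.append(
                HitRecord(o.id, f"nr|{o.id}_3", round(b * 0.97, 1), None, func, lineage)
            )
            if role == "synthase":
                domain_hits.append(DomainHit(o.id, PFAM_AHL_SYNTHASE, 120.0, 1e-30))
            else:
                domain_hits.append(DomainHit(o.id, PFAM_AUTOINDUCER_BINDING, 95.0, 1e-25))
                domain_hits.append(DomainHit(o.id, PFAM_GERE, 60.0, 1e-18))

    target_pair = f"{config.target_taxon[0]}:{config.target_taxon[1]}"
    n_target_contigs = sum(1 for lin in contig_lineage.values() if target_pair in lin)
    truth = SyntheticTruth(
        seed=config.seed,
        config_hash=config.config_hash(),
        roles=roles,
        orf_lineages=orf_lineage,
        contig_lineages=contig_lineage,
        pairs=pairs,
        solo_receptors=solo_receptors,
        unpaired_synthases=unpaired_synthases,
        boxes=boxes,
        receptor_missense=receptor_missense,
        counts={
            "n_luxI": n_pairs + n_lone_syn,
            "n_luxR_paired": n_pairs,
            "n_luxR_solo": len(solo_receptors),
            "n_target_contigs": n_target_contigs,
            "n_boxes": len(boxes),
            "n_contigs": len(contigs),
            "n_orfs": len(orfs),
        },
    )
    return SyntheticCommunity(
        contigs=contigs,
        orfs=orfs,
        hits=hits,
        domain_hits=domain_hits,
        proteins=proteins,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# stress fixtures
# ---------------------------------------------------------------------------


def corrupt_hits(
    hits: Sequence[HitRecord],
    tie_fraction: float = 0.0,
    dropout_fraction: float = 0.0,
    seed: int = 0,
    qs_kos: Optional[frozenset[str]] = None,
) -> tuple[list[HitRecord], dict]:
    """Degrade a hit table with QS/non-QS score ties and whole-ORF dropouts.

    Ties: for the stated fraction of ORFs whose best hit is a QS KO, a
    non-QS-KO row with an equal bitscore is appended (defeating the strict
    best-hit rule). Dropouts: all rows for the stated fraction of ORFs are
    removed. Returns the degraded table and a record of what was done.
    """
    if not (0 <= tie_fraction <= 1 and 0 <= dropout_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    from .qs_gene_screen import QsKoSets

    qs_kos = qs_kos if qs_kos is not None else QsKoSets().all_qs
    rng = np.random.default_rng(seed)
    by_orf: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_orf.setdefault(h.orf_id, []).append(h)
    orf_ids = sorted(by_orf)

    dropped = [o for o in orf_ids if rng.random() < dropout_fraction]
    dropped_set = set(dropped)

    qs_orfs = [
        o
        for o in orf_ids
        if o not in dropped_set
        and any(h.ko_id in qs_kos for h in by_orf[o])
    ]
    tied = [o for o in qs_orfs if rng.random() < tie_fraction]

    out: list[HitRecord] = []
    for o in orf_ids:
        if o in dropped_set:
            continue
        rows = list(by_orf[o])
        if o in tied:
            best_qs = max(h.bitscore for h in rows if h.ko_id in qs_kos)
            out_ko = _DECOY_KOS[int(rng.integers(0, len(_DECOY_KOS)))]
            rows.append(HitRecord(o, f"tie|{o}", best_qs, out_ko, None, None))
        out.extend(rows)
    record = {"tied_orfs": tied, "dropped_orfs": dropped,
              "tie_fraction": tie_fraction, "dropout_fraction": dropout_fraction}
    return out, record


# ---------------------------------------------------------------------------
# standalone scan fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedRegion:
    region: UpstreamRegion
    planted_offset: Optional[int]  # 1-based site start, None = background only
    n_mutations: int
    site: Optional[str]


def generate_planted_regions(
    n_regions: int = 100,
    n_planted: int = 50,
    length: int = 400,
    consensus: str = DEFAULT_CONSENSUS,
    max_mutations: int = 2,
    gc: float = 0.5,
    seed: int = 0,
) -> list[PlantedRegion]:
    """Seeded upstream-region fixtures for scanner recall/false-positive tests.

    The first ``n_planted`` regions carry one copy of the consensus with
    0..max_mutations substitutions at a random offset (random strand);
    the rest are pure background.
    """
    rng = np.random.default_rng(seed)
    width = len(consensus)
    out: list[PlantedRegion] = []
    from .luxbox import revcomp

    for i in range(n_regions):
        seq = _random_dna(rng, length, gc)
        offset = None
        site = None
        n_mut = 0
        if i < n_planted:
            n_mut = int(rng.integers(0, max_mutations + 1))
            site = _mutate_k(consensus, rng, n_mut)
            offset = int(rng.integers(0, length - width)) + 1
            inserted = site if rng.random() < 0.5 else revcomp(site)
            seq = seq[: offset - 1] + inserted + seq[offset - 1 + width :]
        region = UpstreamRegion(
            orf_id=f"region{i + 1:03d}",
            contig_id=f"region{i + 1:03d}",
            genomic_start=1,
            genomic_end=length,
            strand="+",
            sequence=seq,
            clipped=False,
        )
        out.append(PlantedRegion(region=region, planted_offset=offset,
                                 n_mutations=n_mut, site=site))
    return out
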