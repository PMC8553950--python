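"""Lux-box regulon prediction: PWM scanning of upstream regions.

A position weight matrix is built from an aligned library of ~20 bp
imperfect-palindromic lux-box sites. Each ORF's 400 bp upstream region is
scanned on both strands with log2-odds scores against a background model;
site significance is the exact tail probability of the discretized score
distribution under the background, computed by dynamic programming (the
same null FIMO uses). Significant sites (p < 1e-4 by default) are filtered
for imperfect palindromicity and annotated with their genomic location
(intergenic vs intragenic), distance to the start codon, sigma-70 promoter
elements (-35 TTGACA / -10 TATAAT with a 15-19 bp spacer) and a
Shine-Dalgarno ribosome-binding motif.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .formats_io import Contig, MotifLibrary, OrfRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MINUS35_CONSENSUS = "TTGACA"
MINUS10_CONSENSUS = "TATAAT"
SD_CORE = "AGGAGG"


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# motif model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifModel:
    """PWM over ACGT: counts, background, and log2-odds scores.

    log_odds[i, b] = log2( (counts[i, b] + pseudocount) / (N + 4*pseudocount)
                           / background[b] )
    where N is the library size. The N base scores 0 (background-expected).
    """

    counts: np.ndarray  # (width, 4) ints
    pseudocount: float
    background: np.ndarray  # (4,) frequencies
    log_odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be a width x 4 matrix")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if bg.shape != (4,) or np.any(bg <= 0):
            raise ValueError("background must be 4 positive frequencies")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        n = counts[0].sum()
        if not np.allclose(counts.sum(axis=1), n):
            raise ValueError("every counts row must sum to the library size")
        probs = (counts + self.pseudocount) / (n + 4 * self.pseudocount)
        object.__setattr__(self, "log_odds", np.log2(probs / bg))
        object.__setattr__(self, "_caches", {})

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def with_background(self, background: np.ndarray) -> "MotifModel":
        return MotifModel(
            counts=self.counts, pseudocount=self.pseudocount, background=background
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.asarray(self.counts).argmax(axis=1))

    def integer_scores(self, granularity: int) -> tuple[np.ndarray, float, float]:
        """Discretize the log-odds onto a shared integer lattice.

        Every column uses one step ``eps`` (the widest column's range divided
        by ``granularity``) so integer sums track raw score sums. Returns
        (width x 4 int matrix, eps, min_total) where min_total is the sum of
        per-column minima; a raw score s maps to round((s - min_total)/eps).
        """
        if granularity < 100:
            raise ValueError("granularity must be >= 100")
        key = ("int", granularity)
        cache = getattr(self, "_caches")
        if key not in cache:
            lo = self.log_odds
            col_min = lo.min(axis=1)
            span = float((lo.max(axis=1) - col_min).max())
            eps = span / granularity if span > 0 else 1.0
            ints = np.rint((lo - col_min[:, None]) / eps).astype(np.int64)
            cache[key] = (ints, eps, float(col_min.sum()))
        return cache[key]


def build_motif(
    library: MotifLibrary | Sequence[str],
    pseudocount: float = 0.1,
    background: Optional[Sequence[float]] = None,
) -> MotifModel:
    """Tally an aligned site library into a MotifModel.

    Sites must be equal-length over ACGT (ambiguity is not allowed in
    training); background defaults to uniform.
    """
    sites = list(library.sites if isinstance(library, MotifLibrary) else library)
    if len(sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must share one length")
    counts = np.zeros((width, 4), dtype=np.int64)
    for s in sites:
        for i, base in enumerate(s.upper()):
            if base not in BASE_INDEX:
                raise ValueError(f"site {s!r} contains non-ACGT base {base!r}")
            counts[i, BASE_INDEX[base]] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return MotifModel(counts=counts, pseudocount=pseudocount, background=bg)


def score_site(model: MotifModel, site: str) -> float:
    """Sum of per-position log2-odds; N contributes 0 by convention."""
    if len(site) != model.width:
        raise ValueError(
            f"site length {len(site)} != motif width {model.width}"
        )
    total = 0.0
    for i, base in enumerate(site.upper()):
        if base == "N":
            continue
        try:
            total += model.log_odds[i, BASE_INDEX[base]]
        except KeyError:
            raise ValueError(f"invalid base {base!r} in site") from None
    return float(total)


def _survival(model: MotifModel, granularity: int) -> np.ndarray:
    """P(integer score >= k) for k = 0..max, by per-column convolution."""
    key = ("surv", granularity)
    cache = getattr(model, "_caches")
    if key not in cache:
        ints, _, _ = model.integer_scores(granularity)
        bg = np.asarray(model.background, float)
        dist = np.zeros(int(ints.max(axis=1).sum()) + 1)
        dist[0] = 1.0
        top = 0
        for col in range(model.width):
            new = np.zeros_like(dist)
            for b in range(4):
                shift = int(ints[col, b])
                new[shift : shift + top + 1] += bg[b] * dist[: top + 1]
            dist = new
            top += int(ints[col].max())
        cache[key] = np.cumsum(dist[::-1])[::-1]
    return cache[key]


def motif_score_pvalue(model: MotifModel, score: float, granularity: int = 1000) -> float:
    """Exact tail probability P(random score >= score) under the background.

    The score distribution is the discretized lattice from
    ``integer_scores``; the query score is mapped to its nearest lattice
    point. Scores at or below the minimum return 1.0; scores above the
    maximum return the smallest positive mass (never 0).
    """
    surv = _survival(model, granularity)
    _, eps, min_total = model.integer_scores(granularity)
    t = int(round((score - min_total) / eps))
    if t <= 0:
        return 1.0
    if t >= len(surv):
        # smallest achievable positive tail = P(score == max)
        return float(surv[-1])
    return float(surv[t])


# ---------------------------------------------------------------------------
# upstream regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UpstreamRegion:
    """Upstream sequence oriented 5'->3' toward the ORF's start codon."""

    orf_id: str
    contig_id: str
    genomic_start: int  # 1-based inclusive; start > end means empty
    genomic_end: int
    strand: str  # strand of the ORF
    sequence: str
    clipped: bool

    def __len__(self) -> int:
        return len(self.sequence)

    def genomic_interval(self, offset: int, width: int) -> tuple[int, int]:
        """Genomic 1-based interval of a site at 1-based region ``offset``."""
        if self.strand == "+":
            g1 = self.genomic_start + offset - 1
            return g1, g1 + width - 1
        g2 = self.genomic_end - offset + 1
        return g2 - width + 1, g2


def extract_upstream(orf: OrfRecord, contig: Contig, length: int = 400) -> UpstreamRegion:
    """Extract up to ``length`` bp immediately upstream of an ORF.

    Plus-strand ORF at start s: contig positions [max(1, s-length), s-1].
    Minus-strand ORF at end e: positions [e+1, min(L, e+length)],
    reverse-complemented. Regions shorter than ``length`` are flagged
    clipped; an ORF flush with the contig edge yields an empty region.
    """
    if orf.contig_id != contig.id:
        raise ValueError(f"ORF {orf.id} is not on contig {contig.id}")
    L = len(contig)
    if orf.strand == "+":
        g1, g2 = max(1, orf.start - length), orf.start - 1
        seq = contig.sequence[g1 - 1 : g2] if g2 >= g1 else ""
    else:
        g1, g2 = orf.end + 1, min(L, orf.end + length)
        seq = revcomp(contig.sequence[g1 - 1 : g2]) if g2 >= g1 else ""
    clipped = len(seq) < length
    if not seq:
        logger.warning("ORF %s has no upstream sequence on contig %s", orf.id, contig.id)
    return UpstreamRegion(
        orf_id=orf.id,
        contig_id=contig.id,
        genomic_start=g1,
        genomic_end=g2,
        strand=orf.strand,
        sequence=seq,
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    region: UpstreamRegion
    offset: int  # 1-based start of the site within the region
    strand_within_region: str
    site: str  # matched sequence in the reported orientation
    score: float
    p_value: float
    palindrome_mismatches: int


def palindrome_mismatches(site: str) -> int:
    """Positions at which a site differs from its reverse complement.

    Always even for even-length sites (mismatching pairs count twice);
    0 means a perfect palindrome.
    """
    if len(site) % 2:
        raise ValueError("palindromicity is defined for even-length sites")
    if "N" in site.upper():
        raise ValueError("site contains N; palindromicity undefined")
    rc = revcomp(site.upper())
    return sum(1 for a, b in zip(site.upper(), rc) if a != b)


def region_background(region: UpstreamRegion) -> np.ndarray:
    """Add-one-smoothed nucleotide composition of a region (N ignored)."""
    counts = np.ones(4)
    for base in region.sequence:
        idx = BASE_INDEX.get(base)
        if idx is not None:
            counts[idx] += 1
    return counts / counts.sum()


def scan_region(
    model: MotifModel,
    region: UpstreamRegion,
    p_threshold: float = 1e-4,
    granularity: int = 1000,
    background: str = "region",
) -> list[MotifHit]:
    """Score every offset of a region on both strands; keep p < p_threshold.

    ``background`` 'region' rescores against the region's own composition
    (uniform for clipped regions); 'model' keeps the model's background.
    At one offset only the better-scoring orientation is reported (tie: +).
    """
    if len(region) < model.width:
        logger.warning(
            "region for ORF %s (%d bp) shorter than motif width %d; skipped",
            region.orf_id, len(region), model.width,
        )
        return []
    eff = model
    if background == "region" and not region.clipped:
        eff = model.with_background(region_background(region))
    elif background not in ("region", "model"):
        raise ValueError("background must be 'region' or 'model'")
    seq = region.sequence.upper()
    hits: list[MotifHit] = []
    w = model.width
    for o in range(len(seq) - w + 1):
        fwd = seq[o : o + w]
        rev = revcomp(fwd)
        s_fwd = score_site(eff, fwd)
        s_rev = score_site(eff, rev)
        if s_fwd >= s_rev:
            strand, site, score = "+", fwd, s_fwd
        else:
            strand, site, score = "-", rev, s_rev
        p = motif_score_pvalue(eff, score, granularity)
        if p < p_threshold:
            pal = palindrome_mismatches(site) if "N" not in site else w
            hits.append(
                MotifHit(
                    region=region,
                    offset=o + 1,
                    strand_within_region=strand,
                    site=site,
                    score=score,
                    p_value=p,
                    palindrome_mismatches=pal,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# promoter-context annotation
# ---------------------------------------------------------------------------


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _find_hexamers(seq: str, consensus: str, mismatch_max: int) -> list[tuple[int, int]]:
    """(0-based offset, mismatch count) of every acceptable consensus match."""
    out = []
    for i in range(len(seq) - len(consensus) + 1):
        mm = _mismatches(seq[i : i + len(consensus)], consensus)
        if mm <= mismatch_max:
            out.append((i, mm))
    return out


@dataclass(frozen=True)
class PromoterElements:
    minus35_found: bool
    minus10_found: bool
    paired: bool
    minus35_position: Optional[int] = None  # 1-based within the region
    minus10_position: Optional[int] = None
    spacer: Optional[int] = None


def find_promoter_elements(
    region: UpstreamRegion,
    site_offset: int,
    site_width: int,
    mismatch_max: int = 2,
    spacer_range: tuple[int, int] = (15, 19),
) -> PromoterElements:
    """Search downstream of a site for sigma-70 -35/-10 elements.

    TTGACA and TATAAT are matched with up to ``mismatch_max`` mismatches in
    the stretch between the site's 3' edge and the start codon. The
    best-scoring pair with a 15-19 bp spacer (fewest total mismatches, then
    leftmost) is returned; without a compatible pair the elements are
    reported individually as unpaired.
    """
    tail_start = site_offset - 1 + site_width  # 0-based index after the site
    tail = region.sequence.upper()[tail_start:]
    m35 = _find_hexamers(tail, MINUS35_CONSENSUS, mismatch_max)
    m10 = _find_hexamers(tail, MINUS10_CONSENSUS, mismatch_max)
    lo, hi = spacer_range
    best: Optional[tuple[int, int, int, int]] = None  # (mm_total, p35, p10, spacer)
    for p35, mm35 in m35:
        for p10, mm10 in m10:
            spacer = p10 - (p35 + len(MINUS35_CONSENSUS))
            if lo <= spacer <= hi:
                cand = (mm35 + mm10, p35, p10, spacer)
                if best is None or cand < best:
                    best = cand
    to_region = lambda p: tail_start + p + 1  # 1-based region coordinate
    if best is not None:
        _, p35, p10, spacer = best
        return PromoterElements(
            True, True, True, to_region(p35), to_region(p10), spacer
        )
    pos35 = min(m35, key=lambda t: (t[1], t[0]))[0] if m35 else None
    pos10 = min(m10, key=lambda t: (t[1], t[0]))[0] if m10 else None
    return PromoterElements(
        minus35_found=pos35 is not None,
        minus10_found=pos10 is not None,
        paired=False,
        minus35_position=to_region(pos35) if pos35 is not None else None,
        minus10_position=to_region(pos10) if pos10 is not None else None,
    )


def find_shine_dalgarno(
    region: UpstreamRegion,
    core: str = SD_CORE,
    min_run: int = 4,
    spacing: tuple[int, int] = (4, 14),
) -> tuple[bool, Optional[int]]:
    """Look for a ribosome-binding site just upstream of the start codon.

    A hit is a run of >= ``min_run`` consecutive matches to the AGGAGG core
    within the final 20 bp of the region, ending 4-14 nt before the start
    codon. Returns (found, 1-based region position of the run start).
    """
    seq = region.sequence.upper()
    L = len(seq)
    window_start = max(0, L - 20)
    lo, hi = spacing
    for a in range(window_start, L):  # alignment offset of core position 0
        run = 0
        for j in range(len(core)):
            if a + j < L and seq[a + j] == core[j]:
                run += 1
                end = a + j  # 0-based end of current run
                dist = L - (end + 1)
                if run >= min_run and lo <= dist <= hi:
                    return True, end - run + 2  # 1-based run start
            else:
                run = 0
    return False, None


# ---------------------------------------------------------------------------
# regulon prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulonCandidate:
    orf_id: str
    contig_id: str
    hit: MotifHit
    genomic_start: int
    genomic_end: int
    distance_upstream: int
    location_class: str  # intergenic | intragenic
    promoter: PromoterElements
    sd_found: bool
    sd_position: Optional[int]
    shared_bidirectional_with: Optional[str] = None


@dataclass(frozen=True)
class RegulonConfig:
    upstream_length: int = 400
    p_threshold: float = 1e-4
    palindrome_max: int = 8
    granularity: int = 1000
    background: str = "region"
    promoter_mismatch_max: int = 2


def distance_upstream(hit: MotifHit) -> int:
    """Nucleotides strictly between the site's proximal edge and the start codon."""
    return len(hit.region) - (hit.offset + len(hit.site) - 1)


def classify_hit_location(
    hit: MotifHit, orfs: Sequence[OrfRecord]
) -> tuple[str, tuple[int, int]]:
    """Intragenic iff the site's genomic interval overlaps any ORF interval."""
    g1, g2 = hit.region.genomic_interval(hit.offset, len(hit.site))
    for o in orfs:
        if o.contig_id == hit.region.contig_id and o.start <= g2 and g1 <= o.end:
            return "intragenic", (g1, g2)
    return "intergenic", (g1, g2)


def predict_regulon(
    contigs: Sequence[Contig],
    orfs: Sequence[OrfRecord],
    model: MotifModel,
    config: RegulonConfig = RegulonConfig(),
    target_contig_ids: Optional[Iterable[str]] = None,
) -> list[RegulonCandidate]:
    """Full lux-box screen over the upstream regions of a set of ORFs.

    Restrict with ``target_contig_ids`` (e.g. contigs binned to the target
    taxon). One genomic site falling in the upstream regions of two
    divergently transcribed ORFs yields two candidates cross-referenced via
    ``shared_bidirectional_with``. Results are ranked by p-value.
    """
    by_contig = {c.id: c for c in contigs}
    wanted = set(target_contig_ids) if target_contig_ids is not None else None
    candidates: list[RegulonCandidate] = []
    for orf in orfs:
        if wanted is not None and orf.contig_id not in wanted:
            continue
        contig = by_contig.get(orf.contig_id)
        if contig is None:
            raise ValueError(f"ORF {orf.id} references unknown contig {orf.contig_id}")
        region = extract_upstream(orf, contig, config.upstream_length)
        if len(region) < model.width:
            continue
        for hit in scan_region(
            model,
            region,
            p_threshold=config.p_threshold,
            granularity=config.granularity,
            background=config.background,
        ):
            if hit.palindrome_mismatches > config.palindrome_max:
                continue
            loc, (g1, g2) = classify_hit_location(hit, orfs)
            promoter = find_promoter_elements(
                region, hit.offset, model.width, config.promoter_mismatch_max
            )
            sd_found, sd_pos = find_shine_dalgarno(region)
            candidates.append(
                RegulonCandidate(
                    orf_id=orf.id,
                    contig_id=orf.contig_id,
                    hit=hit,
                    genomic_start=g1,
                    genomic_end=g2,
                    distance_upstream=distance_upstream(hit),
                    location_class=loc,
                    promoter=promoter,
                    sd_found=sd_found,
                    sd_position=sd_pos,
                )
            )
    # cross-reference shared bidirectional sites
    by_site: dict[tuple[str, int, int], list[int]] = {}
    for idx, c in enumerate(candidates):
        by_site.setdefault((c.contig_id, c.genomic_start, c.genomic_end), []).append(idx)
    for indices in by_site.values():
        if len(indices) == 2:
            a, b = indices
            if candidates[a].orf_id != candidates[b].orf_id:
                from dataclasses import replace

                candidates[a] = replace(
                    candidates[a], shared_bidirectional_with=candidates[b].orf_id
                )
                candidates[b] = replace(
                    candidates[b], shared_bidirectional_with=candidates[a].orf_id
                )
    candidates.sort(key=lambda c: (c.hit.p_value, c.orf_id, c.genomic_start))
    return candidates


def write_meme_minimal(model: MotifModel, path, name: str = "luxbox") -> None:
    """Serialize the position probability matrix in MEME minimal format."""
    counts = np.asarray(model.counts, float)
    n = counts[0].sum()
    ppm = (counts + model.pseudocount) / (n + 4 * model.pseudocount)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = model.background
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {model.width} "
            f"nsites= {int(n)} E= 0\n"
        )
        for row in ppm:
            fh.write(" " + "  ".join(f"{x:.6f}" for x in row) + "\n")
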