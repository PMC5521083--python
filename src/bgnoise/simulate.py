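"""Synthetic aligned-read simulator with per-process error injection.

The simulator emulates capture-based targeted deep sequencing the way the
protocol actually layers its error processes:

1. *Fragmentation* (acoustic shearing of leukocyte gDNA, or plasma-nuclease
   cleavage of cfDNA): fragment break points are drawn with configurable
   dinucleotide cleavage preferences, and shearing injects oxidative-guanine
   duplex lesions (C:G>A:T and C:G>G:C type, CpG-context-boosted) plus
   break-point-localized A>K substitutions at fragment 5' termini.
2. *Capture*: strand-asymmetric per-C damage (C>A, C>T in reference
   projection for minus-strand baits), applied per captured molecule before
   duplication so all its reads agree.
3. *PCR duplication*: copy number 1 + Poisson(dup_mean - 1), duplicates
   sharing fragment coordinates.
4. *Sequencing run*: independent per-read-base miscalls with a biphasic
   two-point base-quality model.

Every injected lesion is logged in a ground-truth ledger so each estimator in
the analysis layer can be validated by parameter recovery.  Duplex lesions
(oxidation, break-point) live on one strand of the molecule and are read out
only when the read pair derives from that strand; the ledger records both the
lesioned strand and whether it was read out (``on_template``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import io, seqs
from .reads import ReadSet
from .seqs import A, C, G, T


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _default_cleavage() -> dict[str, dict[str, float]]:
    # Acoustic shearing: phosphodiester-bond cleavage preference CG > CA > TA ~ GA,
    # i.e. preferential cuts 5' of A.  Plasma: nuclease cleavage with a mild
    # C-rich preference upstream of the cut, distinct from the acoustic table.
    acoustic = {d: 1.0 for d in seqs.DINUCS}
    acoustic.update({"CG": 4.0, "CA": 3.0, "TA": 2.0, "GA": 2.0})
    plasma = {d: 1.0 for d in seqs.DINUCS}
    plasma.update({"CC": 2.0, "CA": 1.5, "TC": 1.5})
    return {"acoustic": acoustic, "plasma": plasma}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Probabilities are per eligible base (or per eligible fragment end for
    ``p_bp``); rates were chosen to land in the 1e-5 .. 1e-4 per-base range
    characteristic of quality-filtered targeted deep sequencing.
    """

    seed: int = 0
    ref_length: int = 100_000
    gc_fraction: float = 0.41
    cpg_enrichment: float = 1.0
    target_fraction: float = 0.5
    fragment_median: int = 170
    fragment_sd: float = 45.0
    shear_energy: float = 1.0
    cleavage_weights: dict[str, dict[str, float]] = field(default_factory=_default_cleavage)
    p_ox: float = 5.8e-5
    p_ox2: float = 1.0e-5
    ncg_multiplier: float = 5.0
    p_bp: float = 5.0e-4
    p_hs_CA: float = 1.5e-5
    p_hs_CT: float = 6.0e-6
    p_template: float = 6.0e-5
    p_seq: float = 1.0e-3
    q_high_given_error: float = 0.006
    q_low_given_correct: float = 0.13
    q_high: int = 37
    q_low: int = 12
    dup_mean: float = 1.5
    snp_density: float = 5.0e-4
    n_fragments: int = 250_000
    read_length: int = 100
    captured_strand: str = "-"
    somatic_spikes: list[tuple[int, str, float]] = field(default_factory=list)

    def validate(self) -> None:
        probs = {
            "gc_fraction": self.gc_fraction,
            "target_fraction": self.target_fraction,
            "p_ox": self.p_ox, "p_ox2": self.p_ox2, "p_bp": self.p_bp,
            "p_hs_CA": self.p_hs_CA, "p_hs_CT": self.p_hs_CT,
            "p_template": self.p_template, "p_seq": self.p_seq,
            "q_high_given_error": self.q_high_given_error,
            "q_low_given_correct": self.q_low_given_correct,
            "snp_density": self.snp_density,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if self.cpg_enrichment < 0 or self.shear_energy < 0:
            raise InvalidConfigError("cpg_enrichment and shear_energy must be >= 0")
        if self.ncg_multiplier < 0:
            raise InvalidConfigError("ncg_multiplier must be >= 0")
        if self.dup_mean < 1.0:
            raise InvalidConfigError("dup_mean must be >= 1 (copies per unique molecule)")
        if self.ref_length < 10 * self.read_length:
            raise InvalidConfigError(
                f"ref_length={self.ref_length} below 10x read_length={self.read_length}"
            )
        if not 0.0 < self.target_fraction <= 1.0:
            raise InvalidConfigError("target_fraction must be in (0, 1]")
        if self.captured_strand not in ("+", "-"):
            raise InvalidConfigError("captured_strand must be '+' or '-'")
        for mode, table in self.cleavage_weights.items():
            if len(table) != 16 or set(table) != set(seqs.DINUCS):
                raise InvalidConfigError(f"cleavage table '{mode}' must have 16 dinucleotides")
            vals = np.array(list(table.values()), dtype=float)
            if (vals < 0).any():
                raise InvalidConfigError(f"cleavage table '{mode}' has negative weights")
            if not (vals > 0).any():
                raise InvalidConfigError(f"cleavage table '{mode}' has no positive weight")
        for pos, alt, af in self.somatic_spikes:
            if alt not in seqs.BASES or not 0 <= af <= 1 or not 0 <= pos < self.ref_length:
                raise InvalidConfigError(f"bad somatic spike ({pos}, {alt}, {af})")

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["somatic_spikes"] = [list(s) for s in self.somatic_spikes]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "somatic_spikes" in d:
            d["somatic_spikes"] = [tuple(s) for s in d["somatic_spikes"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class ReferenceBundle:
    name: str
    codes: np.ndarray                      # uint8 base codes
    targets: list[tuple[int, int]]         # sorted, non-overlapping, 0-based half-open

    @property
    def sequence(self) -> str:
        return seqs.decode(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def target_mask(self) -> np.ndarray:
        return io.target_mask(self.targets, len(self.codes))

    def write(self, fasta_path: str, bed_path: str) -> None:
        io.write_fasta(fasta_path, self.name, self.sequence)
        io.write_bed(bed_path, self.name, self.targets)

    @classmethod
    def read(cls, fasta_path: str, bed_path: str) -> "ReferenceBundle":
        name, seq = io.read_fasta(fasta_path)
        return cls(name=name, codes=seqs.encode(seq), targets=io.read_bed(bed_path))


@dataclass
class Fragment:
    start: int
    end: int
    sense_strand: str  # which duplex strand the reads of this molecule derive from


@dataclass
class FragmentSet:
    """Columnar set of sheared molecules (0-based half-open coordinates)."""

    start: np.ndarray
    end: np.ndarray
    is_minus: np.ndarray  # True if reads derive from the reference minus strand

    def __len__(self) -> int:
        return len(self.start)

    def __getitem__(self, i: int) -> Fragment:
        return Fragment(int(self.start[i]), int(self.end[i]),
                        "-" if self.is_minus[i] else "+")

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start


TRUTH_COLUMNS = ["molecule_id", "copy", "mate", "pos", "strand", "ref", "alt",
                 "process", "on_template"]


def empty_truth() -> pd.DataFrame:
    return pd.DataFrame({
        "molecule_id": pd.Series(dtype=np.int64),
        "copy": pd.Series(dtype=np.int32),
        "mate": pd.Series(dtype=np.int8),
        "pos": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=object),
        "ref": pd.Series(dtype=object),
        "alt": pd.Series(dtype=object),
        "process": pd.Series(dtype=object),
        "on_template": pd.Series(dtype=bool),
    })


def _truth_frame(mol, pos, strand, ref_codes, alt_codes, process, on_template,
                 copy=None, mate=None) -> pd.DataFrame:
    n = len(pos)
    base = np.array(list(seqs.BASES))
    return pd.DataFrame({
        "molecule_id": np.asarray(mol, dtype=np.int64),
        "copy": np.full(n, -1, np.int32) if copy is None else np.asarray(copy, np.int32),
        "mate": np.zeros(n, np.int8) if mate is None else np.asarray(mate, np.int8),
        "pos": np.asarray(pos, dtype=np.int64),
        "strand": np.asarray(strand, dtype=object),
        "ref": base[np.asarray(ref_codes, dtype=np.intp)],
        "alt": base[np.asarray(alt_codes, dtype=np.intp)],
        "process": process if not np.isscalar(process) else np.repeat(process, n),
        "on_template": np.asarray(on_template, dtype=bool),
    })


@dataclass
class MoleculeSet:
    """Fragments plus the template-visible substitutions accumulated so far."""

    fragments: FragmentSet
    sub_mol: np.ndarray   # int64, sorted weakly by molecule
    sub_pos: np.ndarray   # int64 reference position
    sub_alt: np.ndarray   # uint8 plus-projected alt code

    def __len__(self) -> int:
        return len(self.fragments)


# --------------------------------------------------------------------------
# reference generation
# --------------------------------------------------------------------------

def make_reference(config: SimConfig, name: str = "panel") -> ReferenceBundle:
    """Generate a random reference with tiled target intervals.

    Base composition follows ``gc_fraction``; the CpG dinucleotide frequency is
    scaled to ``cpg_enrichment`` x freq(C) x freq(G) with a first-order Markov
    chain whose stationary composition is preserved exactly.
    """
    config.validate()
    L = config.ref_length
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    m = config.cpg_enrichment
    rng = np.random.default_rng(config.seed)

    if m == 1.0 or p[C] == 0.0 or p[G] == 0.0:
        codes = rng.choice(4, size=L, p=p).astype(np.uint8)
    else:
        pcg = m * p[G]
        if pcg >= 1.0:
            raise InvalidConfigError("cpg_enrichment too large for this composition")
        row_c = p * (1 - pcg) / (1 - p[G])
        row_c[G] = pcg
        row_other = (p - p[C] * row_c) / (1 - p[C])
        if (row_other < 0).any():
            raise InvalidConfigError(
                "cpg_enrichment incompatible with gc_fraction (needs < 1/freq(C))"
            )
        cum_c = np.cumsum(row_c)
        cum_o = np.cumsum(row_other)
        u = rng.random(L)
        out = np.empty(L, dtype=np.uint8)
        out[0] = int(np.searchsorted(np.cumsum(p), u[0], side="right"))
        prev = out[0]
        cc, co = cum_c.tolist(), cum_o.tolist()
        for i in range(1, L):
            ui = u[i]
            row = cc if prev == C else co
            b = 0
            while row[b] < ui and b < 3:
                b += 1
            out[i] = b
            prev = b
        codes = out

    # tile target blocks, keeping a margin so context windows never hit edges
    block = min(1000, max(200, L // 20))
    margin = 200
    step = max(block, int(round(block / config.target_fraction)))
    targets = []
    s = margin
    while s + block <= L - margin:
        targets.append((s, s + block))
        s += step
    if not targets:
        targets = [(margin, L - margin)]
    return ReferenceBundle(name=name, codes=codes, targets=targets)


# --------------------------------------------------------------------------
# fragmentation
# --------------------------------------------------------------------------

def _lognormal_params(median: float, sd: float) -> tuple[float, float]:
    mu = np.log(median)
    ratio2 = (sd / median) ** 2
    w = (1.0 + np.sqrt(1.0 + 4.0 * ratio2)) / 2.0
    return mu, float(np.sqrt(np.log(w)))


def _bond_weights(codes: np.ndarray, table: dict[str, float]) -> np.ndarray:
    """Weight of the phosphodiester bond 5' of each position (W[0] = 0)."""
    w16 = np.empty(16)
    for i, d in enumerate(seqs.DINUCS):
        w16[i] = table[d]
    dinuc = codes[:-1].astype(np.intp) * 4 + codes[1:].astype(np.intp)
    W = np.zeros(len(codes), dtype=float)
    W[1:] = w16[dinuc]
    return W


def draw_fragments(ref: ReferenceBundle, config: SimConfig, n: int,
                   mode: str = "acoustic",
                   rng: np.random.Generator | None = None) -> FragmentSet:
    """Draw ``n`` fragments with cleavage-weighted break points.

    Both cut bonds are sampled proportionally to the mode's dinucleotide
    cleavage table, renormalized over locally available dinucleotides; the
    fragment length keeps the configured log-normal law up to a +/-8 bp end
    jitter used to honor the end-bond preference.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    table_key = "acoustic" if mode == "acoustic" else "plasma"
    table = config.cleavage_weights[table_key]
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = len(ref)
    W = _bond_weights(ref.codes, table)
    min_len = 20
    jitter = 8
    Wstart = W.copy()
    Wstart[L - min_len - jitter:] = 0.0  # room for a valid end cut
    tot = Wstart.sum()
    if tot <= 0:
        raise InvalidConfigError("cleavage weights leave no valid start position")
    starts = rng.choice(L, size=n, p=Wstart / tot)

    mu, sigma = _lognormal_params(config.fragment_median, config.fragment_sd)
    lens = np.rint(np.exp(rng.normal(mu, sigma, size=n))).astype(np.int64)
    lens = np.maximum(lens, min_len)

    offs = np.arange(-jitter, jitter + 1)
    cand = starts[:, None] + lens[:, None] + offs[None, :]
    valid = (cand >= starts[:, None] + min_len) & (cand <= L - 1)
    wc = np.where(valid, W[np.clip(cand, 0, L - 1)], 0.0)
    with np.errstate(divide="ignore"):
        logw = np.where(wc > 0, np.log(wc), -np.inf)
    pick = np.argmax(logw + rng.gumbel(size=wc.shape), axis=1)
    ends = cand[np.arange(n), pick]
    dead = ~np.isfinite(logw[np.arange(n), pick])
    if dead.any():  # no weighted candidate available: clip deterministically
        ends[dead] = np.minimum(starts[dead] + lens[dead], L - 1)
        ends[dead] = np.maximum(ends[dead], starts[dead] + min_len)
    return FragmentSet(
        start=starts.astype(np.int64),
        end=ends.astype(np.int64),
        is_minus=rng.random(n) < 0.5,
    )


# --------------------------------------------------------------------------
# shearing damage
# --------------------------------------------------------------------------

def _iter_covered(start: np.ndarray, end: np.ndarray, batch: int = 20_000):
    """Yield (molecule index, reference position) for every covered base."""
    for i0 in range(0, len(start), batch):
        s = start[i0:i0 + batch]
        e = end[i0:i0 + batch]
        lens = e - s
        off = np.zeros(len(s) + 1, dtype=np.int64)
        np.cumsum(lens, out=off[1:])
        total = int(off[-1])
        mol = np.repeat(np.arange(i0, i0 + len(s), dtype=np.int64), lens)
        pos = np.repeat(s - off[:-1], lens) + np.arange(total, dtype=np.int64)
        yield mol, pos


def _cpg_member(codes: np.ndarray) -> np.ndarray:
    """True where the position's C:G pair belongs to a CpG dinucleotide."""
    member = np.zeros(len(codes), dtype=bool)
    cg = (codes[:-1] == C) & (codes[1:] == G)
    member[:-1] |= cg
    member[1:] |= cg
    return member


def apply_damage(fragments: FragmentSet, ref: ReferenceBundle, config: SimConfig,
                 mode: str = "acoustic",
                 rng: np.random.Generator | None = None,
                 ) -> tuple[MoleculeSet, pd.DataFrame]:
    """Inject fragmentation-step damage (oxidation + break-point A>K).

    ``mode='none'`` models plasma: no shearing, so the oxidation and
    break-point rates are forced to zero and only an empty ledger results.
    """
    if mode not in ("acoustic", "none"):
        raise InvalidConfigError(f"mode must be 'acoustic' or 'none', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codes = ref.codes
    frames: list[pd.DataFrame] = []

    p_ox = config.shear_energy * config.p_ox if mode == "acoustic" else 0.0
    p_ox2 = config.shear_energy * config.p_ox2 if mode == "acoustic" else 0.0
    p_bp = config.p_bp if mode == "acoustic" else 0.0

    if p_ox > 0 or p_ox2 > 0:
        member = _cpg_member(codes)
        mult = np.where(member, config.ncg_multiplier, 1.0)
        for mol, pos in _iter_covered(fragments.start, fragments.end):
            rc = codes[pos]
            gc_mask = (rc == G) | (rc == C)
            mol, pos, rc = mol[gc_mask], pos[gc_mask], rc[gc_mask]
            p1 = np.minimum(p_ox * mult[pos], 1.0)
            p2 = np.minimum(p_ox2 * mult[pos], 1.0)
            u = rng.random(len(pos))
            hit1 = u < p1
            hit2 = (~hit1) & (u < p1 + p2)
            for hit, proc, alt_at_g, alt_at_c in (
                (hit1, "oxidation_CA", T, A),
                (hit2, "oxidation_CG", C, G),
            ):
                if not hit.any():
                    continue
                hm, hp, hr = mol[hit], pos[hit], rc[hit]
                strand = np.where(hr == G, "+", "-").astype(object)
                alt = np.where(hr == G, alt_at_g, alt_at_c).astype(np.uint8)
                on_t = np.where(hr == G, ~fragments.is_minus[hm], fragments.is_minus[hm])
                frames.append(_truth_frame(hm, hp, strand, hr, alt, proc, on_t))

    if p_bp > 0:
        # plus-strand 5' terminus at fragment start
        sp = fragments.start
        a_start = codes[sp] == A
        hit = a_start & (rng.random(len(sp)) < p_bp)
        if hit.any():
            hm = np.flatnonzero(hit)
            alt = np.where(rng.random(len(hm)) < 0.5, G, T).astype(np.uint8)
            frames.append(_truth_frame(
                hm, sp[hm], np.repeat("+", len(hm)).astype(object),
                np.full(len(hm), A), alt, "breakpoint_AK",
                ~fragments.is_minus[hm]))
        # minus-strand 5' terminus at fragment end (minus-strand A = ref T)
        ep = fragments.end - 1
        a_end = codes[ep] == T
        hit = a_end & (rng.random(len(ep)) < p_bp)
        if hit.any():
            hm = np.flatnonzero(hit)
            # minus-strand A>G projects to plus T>C; A>T projects to T>A
            alt = np.where(rng.random(len(hm)) < 0.5, C, A).astype(np.uint8)
            frames.append(_truth_frame(
                hm, ep[hm], np.repeat("-", len(hm)).astype(object),
                np.full(len(hm), T), alt, "breakpoint_AK",
                fragments.is_minus[hm]))

    truth = pd.concat(frames, ignore_index=True) if frames else empty_truth()
    vis = truth[truth["on_template"]]
    base_idx = {b: i for i, b in enumerate(seqs.BASES)}
    molecules = MoleculeSet(
        fragments=fragments,
        sub_mol=vis["molecule_id"].to_numpy(np.int64),
        sub_pos=vis["pos"].to_numpy(np.int64),
        sub_alt=np.array([base_idx[b] for b in vis["alt"]], dtype=np.uint8),
    )
    return molecules, truth


# --------------------------------------------------------------------------
# read generation
# --------------------------------------------------------------------------

def generate_reads(molecules: MoleculeSet, ref: ReferenceBundle, config: SimConfig,
                   sample_name: str,
                   rng: np.random.Generator | None = None,
                   snps: pd.DataFrame | None = None,
                   spikes: list[tuple[int, str, float]] | None = None,
                   ) -> tuple[ReadSet, pd.DataFrame]:
    """Emit aligned paired 100-bp records for a damaged molecule set.

    Applies (in protocol order) uniform template damage, capture-step damage,
    PCR duplication and sequencing-run miscalls with the biphasic quality
    model, then projects each molecule's template strand into a coordinate
    tractable plus-strand SAM representation.  ``snps`` columns: pos, alt, af.
    """
    if len(molecules) == 0:
        raise InvalidConfigError("molecule set is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frags = molecules.fragments
    n_mol = len(frags)
    codes = ref.codes
    frames: list[pd.DataFrame] = []

    sub_mol = [molecules.sub_mol]
    sub_pos = [molecules.sub_pos]
    sub_alt = [molecules.sub_alt]

    # --- uniform template damage (pre-capture, unspecified chemistry) ------
    if config.p_template > 0:
        for mol, pos in _iter_covered(frags.start, frags.end):
            hit = rng.random(len(pos)) < config.p_template
            if not hit.any():
                continue
            hm, hp = mol[hit], pos[hit]
            rc = codes[hp]
            alt = ((rc + 1 + rng.integers(0, 3, size=len(hp))) % 4).astype(np.uint8)
            strand = np.where(frags.is_minus[hm], "-", "+").astype(object)
            frames.append(_truth_frame(hm, hp, strand, rc, alt, "template_uniform",
                                       np.ones(len(hp), bool)))
            sub_mol.append(hm); sub_pos.append(hp); sub_alt.append(alt)

    # --- capture-step (hybrid selection) damage ---------------------------
    if config.p_hs_CA > 0 or config.p_hs_CT > 0:
        src = C if config.captured_strand == "-" else G
        # reference projection: C>A / C>T for minus-strand baits, G>T / G>A
        # for plus-strand baits
        alt1 = A if src == C else T
        alt2 = T if src == C else A
        for mol, pos in _iter_covered(frags.start, frags.end):
            at_src = codes[pos] == src
            mol, pos = mol[at_src], pos[at_src]
            u = rng.random(len(pos))
            h1 = u < config.p_hs_CA
            h2 = (~h1) & (u < config.p_hs_CA + config.p_hs_CT)
            for hit, proc, altc in ((h1, "hybsel_CA", alt1), (h2, "hybsel_CT", alt2)):
                if not hit.any():
                    continue
                hm, hp = mol[hit], pos[hit]
                alt = np.full(len(hp), altc, np.uint8)
                frames.append(_truth_frame(
                    hm, hp, np.repeat(config.captured_strand, len(hp)).astype(object),
                    np.full(len(hp), src), alt, proc, np.ones(len(hp), bool)))
                sub_mol.append(hm); sub_pos.append(hp); sub_alt.append(alt)

    # --- germline SNPs and somatic spikes (molecule-level, both strands) ---
    order = np.argsort(frags.start, kind="stable")
    s_sorted = frags.start[order]
    max_len = int(frags.lengths.max())

    def _carriers(pos: int, af: float) -> np.ndarray:
        lo = np.searchsorted(s_sorted, pos - max_len, side="left")
        hi = np.searchsorted(s_sorted, pos, side="right")
        cand = order[lo:hi]
        cand = cand[frags.end[cand] > pos]
        return cand[rng.random(len(cand)) < af]

    if snps is not None and len(snps):
        base_idx = {b: i for i, b in enumerate(seqs.BASES)}
        for row in snps.itertuples(index=False):
            carr = _carriers(int(row.pos), float(row.af))
            if len(carr) == 0:
                continue
            alt = np.full(len(carr), base_idx[row.alt], np.uint8)
            sub_mol.append(carr)
            sub_pos.append(np.full(len(carr), int(row.pos), np.int64))
            sub_alt.append(alt)

    if spikes:
        base_idx = {b: i for i, b in enumerate(seqs.BASES)}
        for pos, alt_b, af in spikes:
            carr = _carriers(int(pos), float(af))
            if len(carr) == 0:
                continue
            alt = np.full(len(carr), base_idx[alt_b], np.uint8)
            frames.append(_truth_frame(
                carr, np.full(len(carr), int(pos), np.int64),
                np.repeat(".", len(carr)).astype(object),
                np.full(len(carr), codes[int(pos)]), alt, "somatic",
                np.ones(len(carr), bool)))
            sub_mol.append(carr)
            sub_pos.append(np.full(len(carr), int(pos), np.int64))
            sub_alt.append(alt)

    sm = np.concatenate(sub_mol)
    sp_ = np.concatenate(sub_pos)
    sa = np.concatenate(sub_alt)
    sub_order = np.argsort(sm, kind="stable")
    sm, sp_, sa = sm[sub_order], sp_[sub_order], sa[sub_order]

    # --- PCR duplication --------------------------------------------------
    copies = 1 + rng.poisson(config.dup_mean - 1.0, size=n_mol)
    n_pairs = int(copies.sum())
    mol_of_pair = np.repeat(np.arange(n_mol, dtype=np.int64), copies)
    first_pair = np.zeros(n_mol, dtype=np.int64)
    np.cumsum(copies[:-1], out=first_pair[1:])
    copy_of_pair = np.arange(n_pairs, dtype=np.int64) - first_pair[mol_of_pair]

    # --- read layout ------------------------------------------------------
    rl_mol = np.minimum(config.read_length, frags.lengths)
    n_reads = 2 * n_pairs
    r_mol = np.repeat(mol_of_pair, 2)
    r_copy = np.repeat(copy_of_pair, 2).astype(np.int32)
    r_pair = np.repeat(np.arange(n_pairs, dtype=np.int64), 2)
    mate = np.tile(np.array([1, 2], dtype=np.uint8), n_pairs)
    tmin = frags.is_minus[r_mol]
    rl = rl_mol[r_mol]
    rev = ((mate == 1) & tmin) | ((mate == 2) & ~tmin)
    rpos = np.where(rev, frags.end[r_mol] - rl, frags.start[r_mol])

    offsets = np.zeros(n_reads + 1, dtype=np.int64)
    np.cumsum(rl, out=offsets[1:])
    total = int(offsets[-1])
    conc_pos = np.repeat(rpos - offsets[:-1], rl) + np.arange(total, dtype=np.int64)
    seq_flat = codes[conc_pos].copy()

    # imprint template substitutions onto every covering read of the molecule
    for k in range(len(sm)):
        m, p, a = int(sm[k]), int(sp_[k]), sa[k]
        lo = int(first_pair[m]) * 2
        hi = lo + int(copies[m]) * 2
        for r in range(lo, hi):
            d = p - rpos[r]
            if 0 <= d < rl[r]:
                seq_flat[offsets[r] + d] = a

    # --- sequencing-run errors + biphasic qualities -----------------------
    qual_flat = np.empty(total, dtype=np.uint8)
    err_idx_all: list[np.ndarray] = []
    chunk = 1 << 24
    for b0 in range(0, total, chunk):
        b1 = min(b0 + chunk, total)
        nblk = b1 - b0
        err = rng.random(nblk) < config.p_seq
        u = rng.random(nblk)
        q = np.where(u < config.q_low_given_correct, config.q_low, config.q_high)
        widx = np.flatnonzero(err)
        if len(widx):
            cur = seq_flat[b0 + widx]
            seq_flat[b0 + widx] = (cur + 1 + rng.integers(0, 3, size=len(widx))) % 4
            ue = rng.random(len(widx))
            q[widx] = np.where(ue < config.q_high_given_error, config.q_high, config.q_low)
            err_idx_all.append(b0 + widx)
        qual_flat[b0:b1] = q

    if err_idx_all:
        eidx = np.concatenate(err_idx_all)
        eread = np.searchsorted(offsets, eidx, side="right") - 1
        epos = conc_pos[eidx]
        strand = np.where(tmin[eread], "-", "+").astype(object)
        frames.append(_truth_frame(
            r_mol[eread], epos, strand, codes[epos], seq_flat[eidx],
            "seqrun", np.ones(len(eidx), bool),
            copy=r_copy[eread], mate=mate[eread]))

    rs = ReadSet(
        pair_id=r_pair,
        mate=mate,
        pos=rpos.astype(np.int64),
        is_reverse=rev,
        seq=seq_flat,
        qual=qual_flat,
        offsets=offsets,
        molecule_id=r_mol,
        copy=r_copy,
        rname=ref.name,
        sample=sample_name,
    )
    truth = pd.concat(frames, ignore_index=True) if frames else empty_truth()
    return rs, truth


# --------------------------------------------------------------------------
# cohort orchestration
# --------------------------------------------------------------------------

def sample_snp_sites(config: SimConfig, ref: ReferenceBundle,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Polymorphic sites shared by the cohort (pos, ref, alt)."""
    n = int(round(config.snp_density * len(ref)))
    if n == 0:
        return pd.DataFrame(columns=["pos", "ref", "alt"])
    pos = np.sort(rng.choice(len(ref), size=n, replace=False))
    rc = ref.codes[pos]
    alt = (rc + 1 + rng.integers(0, 3, size=n)) % 4
    bases = np.array(list(seqs.BASES))
    return pd.DataFrame({"pos": pos, "ref": bases[rc.astype(np.intp)],
                         "alt": bases[alt.astype(np.intp)]})


def genotype_subject(sites: pd.DataFrame, rng: np.random.Generator,
                     p_het: float = 0.4, p_hom: float = 0.1) -> pd.DataFrame:
    """Per-subject genotypes at the cohort sites (pos, ref, alt, af)."""
    if len(sites) == 0:
        return pd.DataFrame(columns=["pos", "ref", "alt", "af"])
    u = rng.random(len(sites))
    af = np.where(u < p_hom, 1.0, np.where(u < p_hom + p_het, 0.5, 0.0))
    out = sites.assign(af=af)
    return out[out["af"] > 0].reset_index(drop=True)


def simulate_sample(config: SimConfig, ref: ReferenceBundle, mode: str,
                    sample_name: str, rng: np.random.Generator,
                    snps: pd.DataFrame | None = None,
                    spikes: list[tuple[int, str, float]] | None = None,
                    n_fragments: int | None = None,
                    ) -> tuple[ReadSet, pd.DataFrame]:
    """Fragment, damage and sequence one sample; returns reads + truth ledger."""
    n = n_fragments if n_fragments is not None else config.n_fragments
    frags = draw_fragments(ref, config, n, mode="acoustic" if mode == "acoustic" else "plasma",
                           rng=rng)
    molecules, truth_damage = apply_damage(frags, ref, config, mode=mode, rng=rng)
    rs, truth_reads = generate_reads(molecules, ref, config, sample_name, rng=rng,
                                     snps=snps, spikes=spikes)
    truth = pd.concat([truth_damage, truth_reads], ignore_index=True)
    return rs, truth


def simulate_cohort(config: SimConfig, n_pairs: int, outdir: str | None = None,
                    with_fna: bool = True) -> dict:
    """Simulate matched sample triplets for ``n_pairs`` subjects.

    Per subject: plasma-like (no shearing, nuclease cleavage table), PBL-like
    (acoustic shearing), and optionally FNA-like (PBL protocol plus the
    configured somatic spikes).  Germline SNP genotypes are shared within each
    subject's triplet.  If ``outdir`` is given, writes FASTA/BED/SAM, truth
    TSVs, sample metadata and a YAML echo of the configuration.
    """
    if n_pairs < 1:
        raise InvalidConfigError("n_pairs must be >= 1")
    config.validate()
    ref = make_reference(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + 3 * n_pairs * 2)
    snp_rng = np.random.default_rng(children[0])
    sites = sample_snp_sites(config, ref, snp_rng)

    result = {"reference": ref, "snp_sites": sites, "subjects": []}
    sample_rows = []
    child = 1
    for subj in range(n_pairs):
        geno = genotype_subject(sites, np.random.default_rng(children[child])); child += 1
        subject = {"id": f"s{subj:02d}", "snps": geno, "samples": {}}
        plan = [("plasma", "none", None), ("pbl", "acoustic", None)]
        if with_fna:
            plan.append(("fna", "acoustic", config.somatic_spikes))
        for stype, mode, spikes in plan:
            name = f"s{subj:02d}_{stype}"
            rng = np.random.default_rng(children[child]); child += 1
            rs, truth = simulate_sample(config, ref, mode, name, rng,
                                        snps=geno, spikes=spikes)
            subject["samples"][stype] = {"reads": rs, "truth": truth}
            sample_rows.append({"sample": name, "subject": subject["id"],
                                "type": stype, "mode": mode,
                                "n_fragments": config.n_fragments})
        result["subjects"].append(subject)

    if outdir is not None:
        import os
        os.makedirs(outdir, exist_ok=True)
        ref.write(os.path.join(outdir, "reference.fasta"),
                  os.path.join(outdir, "targets.bed"))
        config.to_yaml(os.path.join(outdir, "config.yaml"))
        pd.DataFrame(sample_rows).to_csv(os.path.join(outdir, "samples.tsv"),
                                         sep="\t", index=False)
        for subject in result["subjects"]:
            geno = subject["snps"]
            snp_truth = pd.DataFrame({
                "molecule_id": np.full(len(geno), -1, np.int64),
                "copy": np.full(len(geno), -1, np.int32),
                "mate": np.zeros(len(geno), np.int8),
                "pos": geno["pos"].to_numpy() if len(geno) else np.empty(0, np.int64),
                "strand": ".",
                "ref": geno["ref"] if len(geno) else pd.Series(dtype=object),
                "alt": geno["alt"] if len(geno) else pd.Series(dtype=object),
                "process": "snp",
                "on_template": True,
            })
            for stype, payload in subject["samples"].items():
                name = f"{subject['id']}_{stype}"
                payload["reads"].to_sam(os.path.join(outdir, f"{name}.sam"),
                                        ref.name, len(ref))
                full = pd.concat([payload["truth"], snp_truth], ignore_index=True)
                full[TRUTH_COLUMNS].to_csv(os.path.join(outdir, f"{name}_truth.tsv"),
                                           sep="\t", index=False)
    return result
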