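"""Synthetic-data generator: toy genome, contaminated small-RNA database,
per-sample alignments, clinical covariates and survival times, with truth.

The generator emulates the input universe of a bulk small RNA-seq study of
breast tumors: a multi-contig genome carrying (a) planted genuine small-RNA
loci (unique 26-30 nt sequences, 5'U-enriched, reads stacking tightly at the
5' end), (b) ncRNA and repeat annotation layers whose internal substrings are
registered as *fragment decoys* in the database (their reads come from the
host ncRNA, not an independent locus), (c) a mitochondrial contig, and
entries exercising the placement cap (multicopy) and the no-hit path.
Expression is negative-binomial per sample with grade/ER-linked fold changes;
survival times follow an exponential baseline scaled by quartile-dependent
hazards of a target entry, with independent uniform censoring.

All randomness flows from ``SimConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io
from .types import (
    AlignmentRecord,
    AnnotationFeature,
    DbEntry,
    GenomicInterval,
    PlacedEntry,
    revcomp,
)

NUCS = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset (defaults = test scale)."""

    seed: int
    # genome
    n_chroms: int = 3
    chrom_len: int = 60_000
    mito_chrom: str = "chrM"
    mito_len: int = 3_000
    # database composition
    n_genuine_loci: int = 12
    n_low_abundance: int = 3  # genuine loci kept below the presence criterion
    n_decoy_entries: int = 18
    n_mito_decoys: int = 2
    n_multicopy: int = 1
    multicopy_copies: int = 12  # > the 10-hit cap, so dropped at placement
    n_no_hit: int = 1
    # expression
    genuine_mu: float = 30.0
    low_mu: float = 0.15
    decoy_mu: float = 15.0
    nb_dispersion: float = 0.3
    # read model
    n_samples: int = 60
    read_len_min: int = 20
    read_len_max: int = 32
    five_prime_U_prob: float = 0.9
    stack_tightness: float = 1.0  # SD (nt) of 5'-start jitter
    secondary_rate: float = 0.02
    # conditions and planted effects
    grade_probs: tuple = (0.25, 0.40, 0.35)
    er_pos_prob: float = 0.7
    log2fc_grade3: float = 1.3
    n_grade_linked: int = 3
    log2fc_erneg: float = 1.0
    n_er_linked: int = 2
    # survival
    quartile_log_hazard: tuple = (0.0, 0.3, 0.2, math.log(5.0))
    baseline_hazard: float = 1.0 / 2500.0  # per day
    other_cause_hazard: float = 1.0 / 20000.0
    censoring_fraction: float = 0.3
    follow_up_days: int = 5475

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.five_prime_U_prob, self.er_pos_prob, self.censoring_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")


@dataclass
class Reference:
    """In-memory simulated reference with planted truth."""

    genome: dict[str, str]
    features: list[AnnotationFeature]
    db: list[DbEntry]
    truth: dict
    config: SimConfig
    loci: dict[str, PlacedEntry] = field(default_factory=dict)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCS, size=length))


class _Allocator:
    """Non-overlapping placement of intervals on the main contigs."""

    def __init__(self, rng, chroms: dict[str, int], pad: int = 40):
        self.rng = rng
        self.chroms = chroms
        self.pad = pad
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def take(self, length: int, chrom: str | None = None) -> tuple[str, int]:
        names = sorted(self.chroms)
        for _ in range(2000):
            c = chrom or names[self.rng.integers(len(names))]
            limit = self.chroms[c] - length - self.pad
            if limit <= self.pad:
                continue
            s = int(self.rng.integers(self.pad, limit))
            iv = (s - self.pad, s + length + self.pad)
            if all(e <= iv[0] or s2 >= iv[1] for s2, e in self.occupied[c]):
                self.occupied[c].append((s, s + length))
                return c, s
        raise ValueError(
            "could not allocate a locus: genome too small for the requested content"
        )


def _count_occurrences(genome: dict[str, str], seq: str) -> int:
    rc = revcomp(seq)
    n = 0
    for contig in genome.values():
        for pat in {seq, rc}:
            i = contig.find(pat)
            while i != -1:
                n += 1
                i = contig.find(pat, i + 1)
    return n


def simulate_reference(cfg: SimConfig, out_dir: str | Path | None = None) -> Reference:
    """Generate genome, annotation layers, database FASTA and truth."""
    rng = _rng(cfg, 0)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    arrays = {c: rng.choice(NUCS, size=cfg.chrom_len) for c in chrom_names}
    mito = rng.choice(NUCS, size=cfg.mito_len)
    alloc = _Allocator(rng, {c: cfg.chrom_len for c in chrom_names})

    # --- annotation layers -------------------------------------------------
    feature_spec = [
        ("tRNA", 72, 8),
        ("sncRNA", 120, 6),  # snoRNA-like
        ("miRNA_primary", 90, 6),
        # repeat lengths straddling the 24-bp blacklist bound
        ("repeat", 20, 2),
        ("repeat", 24, 2),
        ("repeat", 25, 2),
        ("repeat", 30, 2),
        ("repeat", 80, 3),
        ("repeat", 200, 2),
    ]
    features: list[AnnotationFeature] = []
    for cls, length, count in feature_spec:
        for k in range(count):
            chrom, start = alloc.take(length)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                AnnotationFeature(
                    GenomicInterval(chrom, start, start + length, strand),
                    cls,
                    name=f"{cls}_{length}_{k}",
                )
            )

    genome = {c: "".join(a) for c, a in arrays.items()}

    db: list[DbEntry] = []
    truth_entries: dict[str, dict] = {}
    loci: dict[str, PlacedEntry] = {}
    idx = 0

    def next_acc() -> str:
        nonlocal idx
        idx += 1
        return f"DB{idx:04d}"

    # --- genuine loci: unique planted sequences ----------------------------
    n_high = cfg.n_genuine_loci - cfg.n_low_abundance
    for i in range(cfg.n_genuine_loci):
        L = int(rng.integers(26, 31))
        chrom, start = alloc.take(L)
        strand = "+" if rng.random() < 0.75 else "-"
        for _ in range(50):
            seq = _rand_seq(rng, L)
            if rng.random() < cfg.five_prime_U_prob:
                seq = "T" + seq[1:]
            arrays[chrom][start : start + L] = list(
                seq if strand == "+" else revcomp(seq)
            )
            genome = {c: "".join(a) for c, a in arrays.items()}
            genome[cfg.mito_chrom] = "".join(mito)
            if _count_occurrences(genome, seq) == 1:
                break
        acc = next_acc()
        mu = cfg.genuine_mu if i < n_high else cfg.low_mu
        link = None
        if i < cfg.n_grade_linked:
            link = ("grade3", cfg.log2fc_grade3)
        elif i < cfg.n_grade_linked + cfg.n_er_linked:
            link = ("er_neg", cfg.log2fc_erneg)
        entry = DbEntry(acc, seq, alias=f"syn-piR-{idx}")
        db.append(entry)
        iv = GenomicInterval(chrom, start, start + L, strand)
        loci[acc] = PlacedEntry(entry, iv, 1)
        truth_entries[acc] = {
            "class": "genuine",
            "locus": [chrom, start, start + L, strand],
            "mu": mu,
            "condition_link": list(link) if link else None,
        }

    genome = {c: "".join(a) for c, a in arrays.items()}
    genome[cfg.mito_chrom] = "".join(mito)

    # --- fragment decoys: substrings of blacklistable features -------------
    hosts = [
        ft
        for ft in features
        if ft.feature_class in {"tRNA", "sncRNA", "miRNA_primary"}
        or (ft.feature_class == "repeat" and ft.length >= 60)
    ]
    for i in range(cfg.n_decoy_entries):
        ft = hosts[i % len(hosts)]
        L = int(rng.integers(26, 31))
        lo, hi = ft.interval.start + 2, ft.interval.end - L - 2
        start = int(rng.integers(lo, max(lo + 1, hi)))
        seq = genome[ft.interval.chrom][start : start + L]
        strand = "+"
        if rng.random() < 0.3:  # some decoys recorded in the other orientation
            seq, strand = revcomp(seq), "-"
        acc = next_acc()
        entry = DbEntry(acc, seq, alias=f"syn-frag-{idx}")
        db.append(entry)
        iv = GenomicInterval(ft.interval.chrom, start, start + L, strand)
        loci[acc] = PlacedEntry(entry, iv, 1)
        truth_entries[acc] = {
            "class": "fragment_decoy",
            "locus": [ft.interval.chrom, start, start + L, strand],
            "mu": cfg.decoy_mu,
            "host_feature": ft.name,
            "host_class": ft.feature_class,
        }

    # --- mitochondrial decoys ----------------------------------------------
    for _ in range(cfg.n_mito_decoys):
        L = int(rng.integers(26, 31))
        start = int(rng.integers(10, cfg.mito_len - L - 10))
        seq = genome[cfg.mito_chrom][start : start + L]
        acc = next_acc()
        entry = DbEntry(acc, seq, alias=f"syn-mt-{idx}")
        db.append(entry)
        loci[acc] = PlacedEntry(
            entry, GenomicInterval(cfg.mito_chrom, start, start + L, "+"), 1
        )
        truth_entries[acc] = {
            "class": "fragment_decoy",
            "locus": [cfg.mito_chrom, start, start + L, "+"],
            "mu": cfg.decoy_mu,
            "host_feature": cfg.mito_chrom,
            "host_class": "mito",
        }

    # --- multicopy entries (exceed the placement cap) -----------------------
    for _ in range(cfg.n_multicopy):
        L = 26
        seq = _rand_seq(rng, L)
        for _ in range(cfg.multicopy_copies):
            chrom, start = alloc.take(L)
            arrays[chrom][start : start + L] = list(seq)
        acc = next_acc()
        db.append(DbEntry(acc, seq, alias=f"syn-multi-{idx}"))
        truth_entries[acc] = {"class": "unplaceable", "locus": None, "mu": 0.0,
                              "reason": "too_many_hits"}

    genome = {c: "".join(a) for c, a in arrays.items()}
    genome[cfg.mito_chrom] = "".join(mito)

    # --- entries absent from the genome -------------------------------------
    for _ in range(cfg.n_no_hit):
        while True:
            seq = _rand_seq(rng, 28)
            if _count_occurrences(genome, seq) == 0:
                break
        acc = next_acc()
        db.append(DbEntry(acc, seq, alias=f"syn-nohit-{idx}"))
        truth_entries[acc] = {"class": "unplaceable", "locus": None, "mu": 0.0,
                              "reason": "no_hit"}

    truth = {"entries": truth_entries, "mito_chrom": cfg.mito_chrom}
    ref = Reference(genome, features, db, truth, cfg, loci)
    if out_dir is not None:
        write_reference(ref, Path(out_dir))
    return ref


def write_reference(ref: Reference, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "ann").mkdir(parents=True, exist_ok=True)
    io.write_fasta(ref.genome, out_dir / "genome.fa")
    io.write_fasta(
        {f"{e.accession} {e.alias}": e.sequence for e in ref.db}, out_dir / "db.fa"
    )
    by_class = {
        "sncrna.gff3": ["sncRNA"],
        "trna.gff3": ["tRNA"],
        "mirna.gff3": ["miRNA_primary"],
    }
    for fname, classes in by_class.items():
        io.write_annotation_gff3(
            [f for f in ref.features if f.feature_class in classes],
            out_dir / "ann" / fname,
        )
    io.write_annotation_bed(
        [f for f in ref.features if f.feature_class == "repeat"],
        out_dir / "ann" / "repeats.bed",
    )


# ---------------------------------------------------------------------------
# Alignments


def sample_conditions(cfg: SimConfig) -> pd.DataFrame:
    """Per-sample tumor grade and ER status (the expression conditions)."""
    rng = _rng(cfg, 1)
    ids = [f"S{i:03d}" for i in range(cfg.n_samples)]
    grade = rng.choice(["I", "II", "III"], size=cfg.n_samples, p=cfg.grade_probs)
    er = np.where(rng.random(cfg.n_samples) < cfg.er_pos_prob, "pos", "neg")
    return pd.DataFrame({"sample_id": ids, "grade": grade, "er": er}).set_index(
        "sample_id"
    )


def _entry_mu(info: dict, grade: str, er: str) -> float:
    mu = info["mu"]
    link = info.get("condition_link")
    if link:
        kind, lfc = link
        if (kind == "grade3" and grade == "III") or (kind == "er_neg" and er == "neg"):
            mu = mu * 2.0**lfc
    return mu


def simulate_alignments(
    cfg: SimConfig,
    ref: Reference,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[AlignmentRecord]], pd.DataFrame, dict]:
    """Draw per-sample NB read counts per locus and emit aligned reads.

    Returns (records per sample, sample conditions, truth updated with the
    drawn counts and the expected-present call for genuine loci). Reads stack
    at the locus 5' end with Normal(0, stack_tightness) jitter; decoy reads
    are kept inside their host feature so they always touch the blacklist.
    """
    conditions = sample_conditions(cfg)
    rng = _rng(cfg, 2)
    chrom_len = {c: len(s) for c, s in ref.genome.items()}
    drawn: dict[str, dict[str, int]] = {
        acc: {} for acc in ref.truth["entries"]
    }
    per_sample: dict[str, list[AlignmentRecord]] = {}
    disp = cfg.nb_dispersion
    feats_by_name = {f.name: f for f in ref.features}

    for sid, cond in conditions.iterrows():
        records: list[AlignmentRecord] = []
        ridx = 0
        for acc in sorted(ref.truth["entries"]):
            info = ref.truth["entries"][acc]
            if info["locus"] is None or info["mu"] <= 0:
                continue
            mu = _entry_mu(info, cond["grade"], cond["er"])
            # NB(mu, dispersion): shape r = 1/disp, p = r / (r + mu)
            r = 1.0 / disp
            c = int(rng.negative_binomial(r, r / (r + mu)))
            drawn[acc][sid] = c
            chrom, lstart, lend, strand = info["locus"]
            host = feats_by_name.get(info.get("host_feature", ""))
            fivep_locus = lend - 1 if strand == "-" else lstart
            for _ in range(c):
                L = int(rng.integers(cfg.read_len_min, cfg.read_len_max + 1))
                jitter = int(round(rng.normal(0.0, cfg.stack_tightness)))
                fp = fivep_locus + (jitter if strand == "+" else -jitter)
                if strand == "-":
                    start, end = fp - L + 1, fp + 1
                else:
                    start, end = fp, fp + L
                # keep reads on the contig; decoy reads inside their host feature
                lo, hi = 0, chrom_len[chrom]
                if host is not None:
                    lo, hi = host.interval.start, host.interval.end
                    if hi - lo < L:
                        lo, hi = 0, chrom_len[chrom]
                shift = max(lo - start, 0) - max(end - hi, 0)
                start, end = start + shift, end + shift
                seq = ref.genome[chrom][start:end]
                if strand == "-":
                    seq = revcomp(seq)
                rid = f"{sid}:{acc}:{ridx}"
                ridx += 1
                records.append(
                    AlignmentRecord(
                        read_id=rid,
                        sample_id=sid,
                        interval=GenomicInterval(chrom, start, end, strand),
                        is_primary=True,
                        mapq=30,
                        read_length=L,
                        read_sequence=seq,
                    )
                )
                if rng.random() < cfg.secondary_rate:
                    # a non-primary alignment elsewhere; must never be counted
                    alt = int(rng.integers(0, chrom_len[chrom] - L))
                    records.append(
                        AlignmentRecord(
                            read_id=rid,
                            sample_id=sid,
                            interval=GenomicInterval(chrom, alt, alt + L, strand),
                            is_primary=False,
                            mapq=0,
                            read_length=L,
                            read_sequence=seq,
                        )
                    )
        per_sample[sid] = records

    truth = dict(ref.truth)
    truth["samples"] = {
        sid: dict(conditions.loc[sid]) for sid in conditions.index
    }
    truth["drawn_counts"] = drawn
    expected_present = {}
    for acc, info in truth["entries"].items():
        if info["class"] != "genuine":
            continue
        n_meet = sum(1 for c in drawn[acc].values() if c >= 2)
        expected_present[acc] = bool(n_meet >= 10)
    truth["expected_present"] = expected_present

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, records in per_sample.items():
            io.write_sam(records, ref.genome, out_dir / f"{sid}.sam")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True, default=str)
    return per_sample, conditions, truth


# ---------------------------------------------------------------------------
# Clinical covariates and survival


def _calibrate_censor_max(t: np.ndarray, fraction: float, cap: float) -> float:
    """c such that C ~ U(0, c) censors the requested fraction of times t."""
    frac = lambda c: float(np.mean(np.minimum(t / c, 1.0))) - fraction  # noqa: E731
    lo, hi = 1e-6, cap
    if frac(hi) > 0:  # even the longest window censors too much
        return cap
    return float(brentq(frac, lo, hi))


def simulate_clinical_survival(
    cfg: SimConfig,
    conditions: pd.DataFrame,
    normalized: pd.DataFrame,
    target_accession: str,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Clinical table with proportional-hazards survival structure.

    Hazards depend on the sample's expression quartile of
    ``target_accession`` via ``cfg.quartile_log_hazard``; censoring is
    independent uniform, calibrated to ``cfg.censoring_fraction``. Recurrence
    always precedes breast-cancer death when both occur.
    """
    from .survival import assign_quartiles  # local import to avoid a cycle

    if cfg.censoring_fraction >= 1.0:
        raise ValueError("censoring fraction 1.0 leaves no events")
    if target_accession not in normalized.index:
        raise ValueError(f"{target_accession} absent from normalized matrix")
    rng = _rng(cfg, 3)
    ids = list(conditions.index)
    n = len(ids)
    quart = assign_quartiles(normalized.loc[target_accession, ids])
    loghaz = {f"Q{i + 1}": lh for i, lh in enumerate(cfg.quartile_log_hazard)}

    er = conditions["er"].to_numpy()
    grade = conditions["grade"].to_numpy()
    pr = np.where(rng.random(n) < 0.2, np.where(er == "pos", "neg", "pos"), er)
    her2 = np.where(rng.random(n) < 0.15, "pos", "neg")
    histology = rng.choice(["ductal", "lobular", "other"], size=n, p=(0.7, 0.2, 0.1))
    tumor_size = rng.choice(["T1", "T2", "T3"], size=n, p=(0.45, 0.4, 0.15))
    nodal = np.where(rng.random(n) < 0.35, "pos", "neg")
    age = np.clip(np.round(rng.normal(58, 10, size=n), 1), 30, 90)
    invasive = rng.random(n) < 0.92
    in_situ = ~invasive
    metastasis = invasive & (rng.random(n) < 0.05)
    rt = np.where(rng.random(n) < 0.6, "yes", "no")
    ct = np.where(rng.random(n) < 0.3, "yes", "no")
    et = np.where((er == "pos") & (rng.random(n) < 0.65), "yes", "no")
    tamoxifen = np.where((et == "yes") & (rng.random(n) < 0.75), "yes", "no")

    rate_bc = cfg.baseline_hazard * np.exp(
        np.array([loghaz[quart[s]] for s in ids])
    )
    t_bc = rng.exponential(1.0 / rate_bc)
    t_other = rng.exponential(1.0 / cfg.other_cause_hazard, size=n)
    t_death = np.minimum(t_bc, t_other)
    cause = np.where(t_bc <= t_other, "breast_cancer", "other")
    rec_frac = rng.uniform(0.5, 0.95, size=n)
    t_rec = np.where(cause == "breast_cancer", t_bc * rec_frac, np.inf)
    # occasional recurrence without (observed) BC death
    extra_rec = (cause == "other") & (rng.random(n) < 0.15)
    t_rec = np.where(extra_rec, t_other * rng.uniform(0.3, 0.9, size=n), t_rec)

    c_max = _calibrate_censor_max(
        t_death, cfg.censoring_fraction, float(cfg.follow_up_days)
    )
    c_i = np.minimum(rng.uniform(0.0, c_max, size=n), cfg.follow_up_days)

    dx = pd.Timestamp("2000-01-01")
    rows = []
    for i, sid in enumerate(ids):
        death_obs = t_death[i] <= c_i[i]
        rec_obs = t_rec[i] <= min(c_i[i], t_death[i])
        death_days = max(2, int(round(t_death[i])))
        rec_days = (
            max(1, min(int(round(t_rec[i])), death_days - 1)) if rec_obs else None
        )
        fu_days = max(1, int(round(c_i[i])))
        rows.append(
            {
                "sample_id": sid,
                "invasive": bool(invasive[i]),
                "in_situ": bool(in_situ[i]),
                "metastasis_at_dx": bool(metastasis[i]),
                "er": er[i],
                "pr": pr[i],
                "her2": her2[i],
                "grade": grade[i],
                "histology": histology[i],
                "tumor_size": tumor_size[i],
                "nodal": nodal[i],
                "age_at_dx": float(age[i]),
                "rt": rt[i],
                "ct": ct[i],
                "et": et[i],
                "tamoxifen": tamoxifen[i],
                "dx_date": dx.date().isoformat(),
                "recurrence_date": (dx + pd.Timedelta(days=rec_days)).date().isoformat()
                if rec_days is not None
                else "",
                "death_date": (dx + pd.Timedelta(days=death_days)).date().isoformat()
                if death_obs
                else "",
                "death_cause": cause[i] if death_obs else "alive",
                "last_followup_date": (dx + pd.Timedelta(days=fu_days)).date().isoformat(),
            }
        )
    clinical = pd.DataFrame(rows)
    if not (clinical["death_cause"] != "alive").any():
        raise ValueError("degenerate hazard configuration: every subject censored")
    truth = {
        "target_accession": target_accession,
        "quartiles": dict(quart),
        "quartile_log_hazard": list(cfg.quartile_log_hazard),
        "censor_max_days": c_max,
    }
    if out_path is not None:
        clinical.to_csv(out_path, sep="\t", index=False)
    return clinical, truth


def load_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key in ("grade_probs", "quartile_log_hazard"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
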