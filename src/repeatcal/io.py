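"""File formats: Stockholm seeds, FASTA, instance tables, profile files,
threshold tables, and benchmark truth (BED + TSV).

Everything here is plain text. Internal coordinates are 1-based inclusive
throughout the package; BED output converts to 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profilecore import ALPHABET, ProfileModel
from .seedforge import InstanceAlignment, SeedAlignment
from .simbench import SyntheticBenchmark, TruthInterval

__all__ = [
    "read_fasta", "write_fasta",
    "read_instances_tsv", "write_instances_tsv",
    "write_stockholm", "read_stockholm",
    "write_aligned_fasta",
    "write_profile", "read_profile",
    "write_thresholds_tsv", "read_thresholds_tsv",
    "write_truth", "read_truth_tsv",
]

_INSTANCE_COLS = [
    "instance_id", "source_id", "start", "end", "strand",
    "divergence", "aligned_instance", "aligned_consensus",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        path, "fasta",
    )


def read_instances_tsv(path) -> list[InstanceAlignment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_INSTANCE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"instance table missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        aln_i = str(r.aligned_instance)
        aln_c = str(r.aligned_consensus)
        cov = getattr(r, "consensus_coverage", None)
        if cov is None or (isinstance(cov, float) and np.isnan(cov)):
            ungapped = sum(c not in "-." for c in aln_c)
            cov = ungapped / max(1, len(aln_c.replace("-", "").replace(".", "")))
        out.append(InstanceAlignment(
            instance_id=str(r.instance_id), source_sequence_id=str(r.source_id),
            start=int(r.start), end=int(r.end), strand=str(r.strand),
            aligned_instance=aln_i, aligned_consensus=aln_c,
            divergence=float(r.divergence), consensus_coverage=float(cov),
            organism=("" if pd.isna(getattr(r, "organism", ""))
                      else str(getattr(r, "organism", ""))),
        ))
    return out


def write_instances_tsv(instances: list[InstanceAlignment], path) -> None:
    pd.DataFrame(
        [(i.instance_id, i.source_sequence_id, i.start, i.end, i.strand,
          i.divergence, i.aligned_instance, i.aligned_consensus,
          i.consensus_coverage, i.organism) for i in instances],
        columns=_INSTANCE_COLS + ["consensus_coverage", "organism"],
    ).to_csv(path, sep="\t", index=False)


def write_stockholm(seed: SeedAlignment, path) -> None:
    """Stockholm 1.0 with a #=GC RF line marking match columns."""
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write(f"#=GF ID {seed.family_id}\n")
        width = max([len(i) for i in seed.member_ids] + [len("#=GC RF")]) + 2
        for name, row in zip(seed.member_ids, seed.members):
            fh.write(f"{name:<{width}}{row}\n")
        fh.write(f"{'#=GC RF':<{width}}{seed.rf}\n")
        fh.write("//\n")


def read_stockholm(path, consensus: str | None = None) -> SeedAlignment:
    """Read a single-alignment Stockholm file written by this package (or
    any file carrying a #=GC RF line with x for match columns).

    If no consensus is supplied, a majority-rule consensus over match
    columns is derived from the members."""
    family_id = "family"
    names: list[str] = []
    rows: dict[str, list[str]] = {}
    rf_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line == "//" or line.startswith("# STOCKHOLM"):
                continue
            if line.startswith("#=GF ID"):
                family_id = line.split()[-1]
            elif line.startswith("#=GC RF"):
                rf_parts.append(line.split()[-1])
            elif line.startswith("#"):
                continue
            else:
                name, seq = line.split()
                if name not in rows:
                    names.append(name)
                    rows[name] = []
                rows[name].append(seq)
    if not names:
        raise ValueError(f"no sequences found in {path}")
    members = ["".join(rows[n]) for n in names]
    rf = "".join(rf_parts)
    if not rf:
        rf = "x" * len(members[0])
    match_idx = [i for i, c in enumerate(rf) if c == "x"]
    counts = np.zeros(len(match_idx), dtype=int)
    derived = []
    for k, i in enumerate(match_idx):
        col = [m[i] for m in members]
        residues = [c for c in col if c not in "-."]
        counts[k] = len(residues)
        if consensus is None:
            best = max(ALPHABET, key=lambda a: col.count(a)) if residues else "N"
            derived.append(best)
    cons = consensus.upper() if consensus is not None else "".join(derived)
    return SeedAlignment(
        family_id=family_id, consensus=cons, members=members,
        member_ids=names, rf=rf, column_counts=counts,
    )


def write_aligned_fasta(seed: SeedAlignment, path) -> None:
    write_fasta(dict(zip(seed.member_ids, seed.members)), path)


def write_profile(profile: ProfileModel, path) -> None:
    """Plain-text profile: header lines, GA/TC lines per taxon, then one
    emission row per match position. Round-trips exactly via repr floats."""
    with open(path, "w") as fh:
        fh.write(f"REPEATCAL-PROFILE 1\n")
        fh.write(f"ID {profile.family_id}\n")
        fh.write(f"LENG {profile.length}\n")
        fh.write(f"TARGET_RE {float(profile.target_re)!r}\n")
        fh.write(f"WEIGHTING {profile.weighting}\n")
        fh.write(f"SCALE {float(profile.scale)!r}\n")
        fh.write(f"GAP_OPEN {float(profile.gap_open)!r}\n")
        fh.write(f"GAP_EXTEND {float(profile.gap_extend)!r}\n")
        fh.write("BG " + " ".join(repr(float(x)) for x in profile.background) + "\n")
        for taxon, cuts in sorted(profile.thresholds.items()):
            fh.write(f"GA {taxon} {float(cuts['GA'])!r}\n")
            fh.write(f"TC {taxon} {float(cuts['TC'])!r}\n")
        fh.write("EMISSIONS\n")
        for i, row in enumerate(profile.emissions, 1):
            fh.write(f"{i} " + " ".join(repr(float(x)) for x in row) + "\n")
        fh.write("//\n")


def read_profile(path) -> ProfileModel:
    meta: dict[str, str] = {}
    thresholds: dict[str, dict[str, float]] = {}
    emissions: list[list[float]] = []
    background = None
    in_emissions = False
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("REPEATCAL-PROFILE"):
            raise ValueError(f"{path} is not a repeatcal profile file")
        for line in fh:
            parts = line.split()
            if not parts or parts[0] == "//":
                continue
            if parts[0] == "EMISSIONS":
                in_emissions = True
                continue
            if in_emissions:
                emissions.append([float(x) for x in parts[1:]])
            elif parts[0] == "BG":
                background = [float(x) for x in parts[1:]]
            elif parts[0] in ("GA", "TC"):
                taxon = parts[1]
                thresholds.setdefault(taxon, {})[parts[0]] = float(parts[2])
            else:
                meta[parts[0]] = parts[1]
    profile = ProfileModel(
        family_id=meta["ID"],
        emissions=np.array(emissions),
        background=np.array(background),
        target_re=float(meta["TARGET_RE"]),
        weighting=meta["WEIGHTING"],
        scale=float(meta["SCALE"]),
        thresholds=thresholds,
        gap_open=float(meta["GAP_OPEN"]),
        gap_extend=float(meta["GAP_EXTEND"]),
    )
    if profile.length != int(meta["LENG"]):
        raise ValueError("profile LENG does not match emission table")
    return profile


def write_thresholds_tsv(results, path) -> None:
    pd.DataFrame(
        [(r.model_id, r.taxon, r.ga, r.tc) for r in results],
        columns=["model_id", "taxon", "GA", "TC"],
    ).to_csv(path, sep="\t", index=False)


def read_thresholds_tsv(path) -> dict[str, dict[str, dict[str, float]]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, dict[str, float]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.model_id), {})[str(r.taxon)] = {
            "GA": float(r.GA), "TC": float(r.TC),
        }
    return out


def write_truth(bench: SyntheticBenchmark, bed_path, tsv_path=None,
                seq_id: str = "benchmark") -> None:
    """Truth intervals as BED6 (0-based half-open) and, optionally, a TSV
    with model coordinates and divergence."""
    with open(bed_path, "w") as fh:
        for t in bench.truth:
            fh.write(f"{seq_id}\t{t.start - 1}\t{t.end}\t{t.family_id}\t"
                     f"0\t{t.strand}\n")
    if tsv_path is not None:
        pd.DataFrame(
            [(t.kind, t.family_id, t.start, t.end, t.strand,
              t.model_from, t.model_to, t.divergence) for t in bench.truth],
            columns=["kind", "family_id", "start", "end", "strand",
                     "model_from", "model_to", "divergence"],
        ).to_csv(tsv_path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TruthInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthInterval(kind=str(r.kind), family_id=str(r.family_id),
                      start=int(r.start), end=int(r.end), strand=str(r.strand),
                      model_from=int(r.model_from), model_to=int(r.model_to),
                      divergence=float(r.divergence))
        for r in df.itertuples()
    ]
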