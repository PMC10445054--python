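"""Reading and writing spectra, popmaps, demes descriptions and reports.

Supported formats: the plain-text frequency-spectrum dialect (``.fs``), VCF
with diploid genotypes plus a two-column sample-to-population map, YAML
demographic-history descriptions following the demes specification, and JSON
run reports.
"""

from __future__ import annotations

import json
import logging
import shlex

import numpy as np
import yaml

from .demography import (CONSTANT, DemographicHistory, UnitScaling,
                         size_trajectory)
from .spectrum import AFS, fold as fold_afs, projection_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_fs", "write_fs", "read_popmap", "afs_from_vcf",
    "history_to_demes_dict", "write_history_yaml", "write_report",
]


# ---------------------------------------------------------------------------
# fs dialect


def read_fs(path) -> AFS:
    """Read a frequency spectrum from the fs text dialect.

    Line 1: shape integers, an optional ``folded``/``unfolded`` token and
    optional quoted population labels.  Line 2: row-major array values.
    Line 3 (optional): row-major 0/1 mask, 1 = masked.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty spectrum file")
    header = shlex.split(lines[0])
    shape = []
    rest = []
    for k, tok in enumerate(header):
        try:
            shape.append(int(tok))
        except ValueError:
            rest = header[k:]
            break
    if not shape:
        raise ValueError(f"{path}: header carries no shape integers")
    folded = False
    labels = None
    if rest:
        tok, rest = rest[0], rest[1:]
        if tok == "folded":
            folded = True
        elif tok == "unfolded":
            folded = False
        else:
            raise ValueError(f"{path}: unknown folding token {tok!r}")
        if rest:
            labels = tuple(rest)
    if len(lines) < 2:
        raise ValueError(f"{path}: missing data line")
    values = np.array([float(x) for x in lines[1].split()])
    expected = int(np.prod(shape))
    if values.size != expected:
        raise ValueError(
            f"{path}: {values.size} values but shape {tuple(shape)} "
            f"needs {expected}")
    data = values.reshape(shape)
    mask = None
    if len(lines) >= 3:
        flags = np.array([int(x) for x in lines[2].split()])
        if flags.size != expected:
            raise ValueError(
                f"{path}: {flags.size} mask entries but shape {tuple(shape)} "
                f"needs {expected}")
        mask = flags.reshape(shape).astype(bool)
    return AFS(data, folded=folded, mask=mask, pop_labels=labels)


def write_fs(afs: AFS, path):
    """Write a spectrum in the fs text dialect (17 significant digits)."""
    header = " ".join(str(s) for s in afs.data.shape)
    header += " folded" if afs.folded else " unfolded"
    if afs.pop_labels:
        header += " " + " ".join(f'"{l}"' for l in afs.pop_labels)
    data = " ".join(f"{x:.17g}" for x in afs.data.reshape(-1))
    mask = " ".join("1" if m else "0" for m in afs.mask.reshape(-1))
    with open(path, "w") as fh:
        fh.write(header + "\n" + data + "\n" + mask + "\n")


# ---------------------------------------------------------------------------
# VCF -> AFS


def read_popmap(path) -> dict:
    """Two-column sample/population file; order defines the AFS axis order."""
    popmap = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed popmap line {ln!r}")
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise ValueError(f"{path}: empty popmap")
    return popmap


def afs_from_vcf(vcf_path, popmap, sample_sizes=None, folded=False,
                 exclude=(), return_stats=False):
    """Tally a (joint) AFS from biallelic SNPs in a VCF file.

    The derived allele is ALT unless an ``AA`` INFO field matching REF or
    ALT is present; without ancestral information only a folded spectrum can
    be requested.  With ``sample_sizes`` (haploid, per population) set, sites
    with missing genotypes are projected down hypergeometrically; otherwise
    incompletely called sites are skipped.
    """
    import pysam

    pops = []
    for sample, pop in popmap.items():
        if pop not in pops and pop not in exclude:
            pops.append(pop)
    if not pops:
        raise ValueError("no populations left after exclusion")
    members = {p: [s for s, q in popmap.items() if q == p] for p in pops}

    vcf = pysam.VariantFile(vcf_path)
    vcf_samples = set(vcf.header.samples)
    missing = [s for p in pops for s in members[p] if s not in vcf_samples]
    if missing:
        raise ValueError(f"popmap samples absent from VCF: {sorted(missing)}")

    full = {p: 2 * len(members[p]) for p in pops}
    if sample_sizes is None:
        target = [full[p] for p in pops]
        project_missing = False
    else:
        target = [int(n) for n in np.atleast_1d(sample_sizes)]
        if len(target) != len(pops):
            raise ValueError("one target sample size per population required")
        for p, t in zip(pops, target):
            if t > full[p]:
                raise ValueError(f"target size {t} exceeds {full[p]} haploids "
                                 f"available for population {p}")
        project_missing = True

    data = np.zeros([t + 1 for t in target])
    stats = {"sites": 0, "used": 0, "multiallelic": 0, "missing_skipped": 0,
             "bad_ancestral": 0}
    for rec in vcf:
        stats["sites"] += 1
        if rec.alts is None or len(rec.alts) != 1:
            stats["multiallelic"] += 1
            continue
        aa = rec.info.get("AA") if "AA" in rec.info else None
        if isinstance(aa, tuple):
            aa = aa[0]
        if aa is not None:
            aa = str(aa).upper()
        swap = False
        if aa is None:
            if not folded:
                raise ValueError(
                    "unfolded spectrum requested but the VCF carries no AA "
                    "(ancestral allele) INFO field")
        elif aa == str(rec.alts[0]).upper():
            swap = True           # ALT is ancestral; REF is derived
        elif aa != str(rec.ref).upper():
            stats["bad_ancestral"] += 1
            continue
        derived = []
        called = []
        for p in pops:
            d = c = 0
            for s in members[p]:
                for allele in rec.samples[s]["GT"]:
                    if allele is None:
                        continue
                    c += 1
                    if allele > 0:
                        d += 1
            if swap:
                d = c - d
            derived.append(d)
            called.append(c)
        if all(c == f for c, f in zip(called, (full[p] for p in pops))) and \
                not project_missing:
            data[tuple(derived)] += 1.0
            stats["used"] += 1
        elif project_missing:
            if any(c < t for c, t in zip(called, target)):
                stats["missing_skipped"] += 1
                continue
            weight = 1.0
            vecs = [projection_matrix(c, t)[d]
                    for c, t, d in zip(called, target, derived)]
            contrib = vecs[0]
            for v in vecs[1:]:
                contrib = np.multiply.outer(contrib, v)
            data += weight * contrib
            stats["used"] += 1
        else:
            stats["missing_skipped"] += 1
    logger.info("VCF %s: %d sites, %d used, %d multiallelic skipped, %d with "
                "unusable ancestral allele, %d skipped for missing genotypes",
                vcf_path, stats["sites"], stats["used"], stats["multiallelic"],
                stats["bad_ancestral"], stats["missing_skipped"])
    afs = AFS(data, folded=False, pop_labels=tuple(pops))
    if folded:
        afs = fold_afs(afs)
    return (afs, stats) if return_stats else afs


# ---------------------------------------------------------------------------
# demes output


def history_to_demes_dict(history: DemographicHistory,
                          scaling: UnitScaling | None = None) -> dict:
    """Express a physical-unit history as a demes-specification dictionary."""
    if history.units != "physical":
        raise ValueError("demes output requires physical units")
    if history.selection_gamma is not None or history.dominance_h is not None:
        raise ValueError("selection is not representable here")

    labels = history.pop_labels or (
        ("pop0", "pop1") if history.n_pops == 2 else ("pop0",))
    epochs = history.epochs()
    split = history.split()
    total = history.total_time()

    # absolute end times (before present) per event
    end_times = []
    t = total
    for ep in epochs:
        t -= ep.duration
        end_times.append(max(t, 0.0))

    def epoch_entry(ep, index, pop, start_size):
        entry = {
            "end_time": end_times[index],
            "start_size": float(start_size) if ep.dynamics[pop] != CONSTANT
            else float(ep.end_sizes[pop]),
            "end_size": float(ep.end_sizes[pop]),
            "size_function": ep.dynamics[pop],
        }
        if ep.dynamics[pop] == CONSTANT:
            entry["start_size"] = float(ep.end_sizes[pop])
        return entry

    demes_list = []
    migrations = []
    if split is None:
        name = labels[0]
        entries = []
        first_end = total if epochs else 0.0
        entries.append({"end_time": first_end, "start_size": float(history.N_anc),
                        "end_size": float(history.N_anc),
                        "size_function": "constant"})
        sizes = (history.N_anc,)
        for k, ep in enumerate(epochs):
            entries.append(epoch_entry(ep, k, 0, sizes[0]))
            sizes = size_trajectory(ep, sizes, ep.duration)
        demes_list.append({"name": name, "epochs": entries})
    else:
        split_index = history.events.index(split)
        pre = [e for e in history.events[:split_index]]
        post = [e for e in history.events[split_index + 1:]]
        t_split = sum(e.duration for e in post)
        anc_entries = [{"end_time": (total if pre else t_split),
                        "start_size": float(history.N_anc),
                        "end_size": float(history.N_anc),
                        "size_function": "constant"}]
        sizes = (history.N_anc,)
        for k, ep in enumerate(pre):
            anc_entries.append(epoch_entry(ep, k, 0, sizes[0]))
            sizes = size_trajectory(ep, sizes, ep.duration)
        demes_list.append({"name": "anc", "epochs": anc_entries})
        child_sizes = split.child_start_sizes(sizes[split.parent_index])
        for pop in range(2):
            entries = []
            s = child_sizes
            for k, ep in enumerate(post):
                entries.append(epoch_entry(ep, len(pre) + k, pop, s[pop]))
                s = size_trajectory(ep, s, ep.duration)
            demes_list.append({"name": labels[pop], "ancestors": ["anc"],
                               "start_time": t_split, "epochs": entries})
        t_hi = t_split
        for k, ep in enumerate(post):
            t_lo = end_times[len(pre) + k]
            if ep.migration is not None:
                for dest in range(2):
                    for source in range(2):
                        rate = ep.migration[dest][source]
                        if dest != source and rate > 0:
                            migrations.append({
                                "source": labels[source], "dest": labels[dest],
                                "rate": float(rate),
                                "start_time": t_hi, "end_time": t_lo,
                            })
            t_hi = t_lo

    doc = {"time_units": "generations", "demes": demes_list}
    if migrations:
        doc["migrations"] = migrations
    if scaling is not None:
        doc["metadata"] = {
            "mutation_rate": scaling.mu,
            "sequence_length": float(scaling.L),
            "generation_time_years": scaling.generation_time,
        }
    return doc


def write_history_yaml(history: DemographicHistory, scaling, path):
    """Write a demes-specification YAML description of a history."""
    doc = history_to_demes_dict(history, scaling)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# JSON report


def write_report(result, path):
    """JSON report with parameters in both unit systems; stable key order."""
    doc = result.report_dict()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
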