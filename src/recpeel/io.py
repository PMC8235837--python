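"""Plain-text readers and writers.

Primary dialects (whitespace/tab delimited):

* pedigree: ``id sire dam [sex] [line]`` per line, ``0`` = unknown parent,
  sex in ``{F, M, 0}``;
* genotypes: ``id`` followed by one dosage code per mapped locus, codes in
  ``{0, 1, 2, 9}`` (9 = missing), one row per individual;
* marker map: ``id chromosome position_bp``;
* genetic map: TSV with chromosome, interval_start_bp, interval_end_bp
  (half-open), cM, cM_per_Mb and sex columns, plus one totals row per
  chromosome.

A PLINK .ped/.map import shim normalises into the primary containers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GeneticMap,
    GenotypeMatrix,
    MarkerMap,
    MISSING,
    Pedigree,
    PedigreeError,
)

_SEX = {"F": "F", "M": "M", "0": "U", "U": "U"}


class FormatError(ValueError):
    """Malformed input file, with the offending location in the message."""


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a whitespace-delimited pedigree file.

    Parents referenced but never listed are added implicitly as founders
    (their sex is inferred from the role they appear in).  Raises
    :class:`FormatError` on malformed rows and :class:`PedigreeError` on
    duplicates or cycles.
    """
    records: list[tuple[str, str, str, str, str]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 3:
                raise FormatError(
                    f"{path}:{ln}: expected 'id sire dam [sex] [line]', got {raw!r}"
                )
            ident, sire, dam = tokens[:3]
            sex = tokens[3] if len(tokens) > 3 else "0"
            line = tokens[4] if len(tokens) > 4 else "1"
            if sex not in _SEX:
                raise FormatError(f"{path}:{ln}: invalid sex token {sex!r}")
            records.append((ident, sire, dam, _SEX[sex], line))
    ids = [r[0] for r in records]
    seen = set()
    for i in ids:
        if i in seen:
            raise PedigreeError(f"duplicate individual id: {i!r}")
        seen.add(i)
    # implicit founders for referenced-but-unlisted parents
    implied_sex = {}
    for _, sire, dam, _, _ in records:
        if sire != "0" and sire not in seen:
            implied_sex.setdefault(sire, "M")
        if dam != "0" and dam not in seen:
            implied_sex.setdefault(dam, "F")
    founders = [(p, "0", "0", s, "1") for p, s in implied_sex.items()]
    records = founders + records
    ids = [r[0] for r in records]
    index = {ident: k for k, ident in enumerate(ids)}
    sire = np.array([index[r[1]] if r[1] != "0" else -1 for r in records])
    dam = np.array([index[r[2]] if r[2] != "0" else -1 for r in records])
    sex = np.array([r[3] for r in records])
    line = np.array([r[4] for r in records], dtype=object)
    return Pedigree(ids=ids, sire=sire, dam=dam, sex=sex, line=line)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, ident in enumerate(pedigree.ids):
            s = pedigree.ids[pedigree.sire[i]] if pedigree.sire[i] >= 0 else "0"
            d = pedigree.ids[pedigree.dam[i]] if pedigree.dam[i] >= 0 else "0"
            sex = pedigree.sex[i] if pedigree.sex[i] in ("F", "M") else "0"
            fh.write(f"{ident} {s} {d} {sex} {pedigree.line[i]}\n")


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read ``id chromosome position`` rows."""
    ids, chroms, pos = [], [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 3:
                raise FormatError(f"{path}:{ln}: expected 'id chromosome position'")
            ids.append(tokens[0])
            chroms.append(tokens[1])
            try:
                pos.append(int(tokens[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad position {tokens[2]!r}") from exc
    return MarkerMap(ids=ids, chromosome=np.array(chroms, dtype=object),
                     position=np.array(pos))


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, ident in enumerate(marker_map.ids):
            fh.write(f"{ident} {marker_map.chromosome[i]} {marker_map.position[i]}\n")


def read_genotypes(
    path: str | Path,
    marker_map: MarkerMap,
    pedigree: Pedigree | None = None,
) -> GenotypeMatrix:
    """Read one dosage row per individual, aligned to the marker map.

    If a pedigree is given, rows are reordered to pedigree order and
    individuals absent from the file become all-missing ("ungenotyped").
    """
    L = len(marker_map)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) - 1 != L:
                raise FormatError(
                    f"{path}:{ln}: expected {L} genotype codes, got {len(tokens) - 1}"
                )
            try:
                row = np.array(tokens[1:], dtype=np.int64)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric genotype code") from exc
            bad = ~np.isin(row, [0, 1, 2, MISSING])
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{path}:{ln}: invalid genotype code {row[j]} at locus {j + 1}"
                )
            ids.append(tokens[0])
            rows.append(row.astype(np.uint8))
    calls = np.vstack(rows) if rows else np.empty((0, L), dtype=np.uint8)
    missing_frac = (calls == MISSING).mean(axis=1) if len(rows) else np.empty(0)
    panel = np.where(
        missing_frac >= 1.0, "ungenotyped", np.where(missing_frac >= 0.5, "low", "high")
    ).astype(object)
    gm = GenotypeMatrix(ids=ids, calls=calls, panel=panel)
    return gm.aligned_to(pedigree) if pedigree is not None else gm


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, ident in enumerate(genotypes.ids):
            fh.write(ident + " " + " ".join(map(str, genotypes.calls[i])) + "\n")


def write_genetic_map(map_est: GeneticMap, path: str | Path) -> None:
    """Write per-interval cM plus a totals row per chromosome.

    The map must carry marker bp positions.  Intervals are half-open
    ``[start, end)``; the totals row spans the whole chromosome and its cM
    equals the column sum.
    """
    if map_est.positions is None:
        raise ValueError("genetic map has no bp positions to write")
    pos = map_est.positions
    with open(path, "w") as fh:
        fh.write("chromosome\tinterval_start_bp\tinterval_end_bp\tcM\tcM_per_Mb\tsex\trow\n")
        for j, d in enumerate(map_est.interval_cm):
            mb = (pos[j + 1] - pos[j]) / 1e6
            rate = d / mb if mb > 0 else float("nan")
            fh.write(
                f"{map_est.chromosome}\t{pos[j]}\t{pos[j + 1]}\t{d:.10g}\t{rate:.10g}\t"
                f"{map_est.sex}\tinterval\n"
            )
        span_mb = (pos[-1] - pos[0]) / 1e6
        total = map_est.total_cm
        fh.write(
            f"{map_est.chromosome}\t{pos[0]}\t{pos[-1]}\t{total:.10g}\t"
            f"{total / span_mb:.10g}\t{map_est.sex}\ttotal\n"
        )


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a genetic map written by :func:`write_genetic_map`."""
    df = pd.read_csv(path, sep="\t")
    chroms = df["chromosome"].astype(str).unique()
    if len(chroms) != 1:
        raise FormatError(f"{path}: expected a single chromosome, got {list(chroms)}")
    intervals = df[df["row"] == "interval"]
    total_rows = df[df["row"] == "total"]
    if len(total_rows) != 1:
        raise FormatError(f"{path}: expected exactly one totals row")
    d = intervals["cM"].to_numpy(dtype=float)
    positions = np.concatenate(
        [
            intervals["interval_start_bp"].to_numpy(dtype=np.int64),
            intervals["interval_end_bp"].to_numpy(dtype=np.int64)[-1:],
        ]
    )
    total = float(total_rows["cM"].iloc[0])
    if abs(total - d.sum()) > 1e-6 * max(1.0, total):
        raise FormatError(f"{path}: totals row does not match the interval sum")
    return GeneticMap(
        chromosome=str(chroms[0]),
        interval_cm=d,
        sex=str(intervals["sex"].iloc[0]),
        positions=positions,
    )


def write_estimates(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a per-individual/per-gamete estimates table as TSV."""
    frame.to_csv(path, sep="\t", index=False)


def read_plink(ped_path: str | Path, map_path: str | Path) -> tuple[
    Pedigree, GenotypeMatrix, MarkerMap
]:
    """Import PLINK .ped/.map files, normalising to the primary containers.

    Alleles at each locus are coded against the alphabetically larger
    observed allele (its count is the dosage); ``0`` alleles mean missing.
    Sex codes 1/2 map to M/F.
    """
    ids, chroms, pos = [], [], []
    with open(map_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if len(tokens) < 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 columns")
            chroms.append(tokens[0])
            ids.append(tokens[1])
            pos.append(int(tokens[3]))
    marker_map = MarkerMap(
        ids=ids, chromosome=np.array(chroms, dtype=object), position=np.array(pos)
    )
    L = len(marker_map)
    ped_rows = []
    allele_rows = []
    with open(ped_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * L:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * L} columns, got {len(tokens)}"
                )
            fid, iid, pid, mid, sex_code, _pheno = tokens[:6]
            sex = {"1": "M", "2": "F"}.get(sex_code, "U")
            ped_rows.append((iid, pid if pid != "0" else "0",
                             mid if mid != "0" else "0", sex, fid))
            allele_rows.append(tokens[6:])
    n = len(ped_rows)
    calls = np.full((n, L), MISSING, dtype=np.uint8)
    alleles = np.array(allele_rows, dtype=object).reshape(n, L, 2) if n else None
    for j in range(L):
        if n == 0:
            break
        col = alleles[:, j, :]
        observed = sorted({a for a in col.ravel() if a != "0"})
        if not observed:
            continue
        counted = observed[-1]  # alphabetically larger allele
        valid = (col != "0").all(axis=1)
        calls[valid, j] = (col[valid] == counted).sum(axis=1)
    index = {r[0] for r in ped_rows}
    implied = {}
    for _, pid, mid, _, _ in ped_rows:
        if pid != "0" and pid not in index:
            implied.setdefault(pid, "M")
        if mid != "0" and mid not in index:
            implied.setdefault(mid, "F")
    all_rows = [(p, "0", "0", s, "1") for p, s in implied.items()] + ped_rows
    ped_ids = [r[0] for r in all_rows]
    lookup = {ident: k for k, ident in enumerate(ped_ids)}
    pedigree = Pedigree(
        ids=ped_ids,
        sire=np.array([lookup[r[1]] if r[1] != "0" else -1 for r in all_rows]),
        dam=np.array([lookup[r[2]] if r[2] != "0" else -1 for r in all_rows]),
        sex=np.array([r[3] for r in all_rows]),
        line=np.array([r[4] for r in all_rows], dtype=object),
    )
    missing_frac = (calls == MISSING).mean(axis=1) if n else np.empty(0)
    panel = np.where(
        missing_frac >= 1.0, "ungenotyped", np.where(missing_frac >= 0.5, "low", "high")
    ).astype(object)
    genotypes = GenotypeMatrix(
        ids=[r[0] for r in ped_rows], calls=calls, panel=panel
    ).aligned_to(pedigree)
    return pedigree, genotypes, marker_map
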