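"""File formats, site filtering and allele-frequency estimation.

The tool consumes the beagle genotype-likelihood dialect produced by ANGSD:
a tab-separated table with a header, one row per diallelic site, columns
``marker allele1 allele2`` followed by three genotype-likelihood columns per
individual (ordered: homozygous allele1, heterozygous, homozygous allele2).
Marker ids carry the coordinate as ``chrom_pos`` (split on the last
underscore, since contig names may themselves contain underscores).
Frequency files hold one allele1 frequency per line, in site order.

Also here: minor-allele-frequency filtering, distance-based thinning (a
cheap stand-in for LD pruning), an EM estimator of allele frequencies from
the genotype likelihoods of all individuals, genetic-map handling, and the
writers for the per-site, segment and parameter outputs.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .ibd_model import PairGL, SiteTable, genotype_prior
from .segments import IBDSegment

__all__ = [
    "BeagleDataset",
    "read_beagle",
    "write_beagle",
    "read_freqs",
    "write_freqs",
    "filter_sites",
    "thin_sites",
    "estimate_freqs_em",
    "read_genetic_map",
    "genetic_distances",
    "write_outputs",
    "read_sites_tsv",
    "read_segments_bed",
]

_ALLELE_CODES = {"0": 0, "1": 1, "2": 2, "3": 3, "A": 0, "C": 1, "G": 2, "T": 3}


class BeagleFormatError(ValueError):
    """Malformed beagle/frequency input; message carries the line number."""


@dataclass
class BeagleDataset:
    """Parsed beagle genotype-likelihood table.

    ``gls`` has shape (N individuals, L sites, 3); column g holds the
    likelihood of the data given g copies of allele1 (the model's A allele).
    """

    markers: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    gls: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.gls.shape[1]

    @property
    def n_ind(self) -> int:
        return self.gls.shape[0]

    def pair(self, a: int, b: int) -> PairGL:
        """Genotype likelihoods of individuals ``a`` and ``b`` (0-based)."""
        n = self.n_ind
        if not (0 <= a < n and 0 <= b < n):
            raise IndexError(f"pair indices must lie in [0, {n}), got {a}, {b}")
        if a == b:
            raise ValueError("the two individuals of a pair must differ")
        return PairGL(self.gls[a].copy(), self.gls[b].copy())

    def subset(self, idx: np.ndarray) -> "BeagleDataset":
        return BeagleDataset(
            self.markers[idx],
            self.allele1[idx],
            self.allele2[idx],
            self.gls[:, idx],
            self.chrom[idx],
            self.pos[idx],
        )


def _open_text(path, mode: str = "rt"):
    """Open plain or gzipped text transparently (checks the magic bytes)."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_marker(marker: str, lineno: int) -> tuple[str, int]:
    chrom, _, pos = marker.rpartition("_")
    if not chrom:
        raise BeagleFormatError(
            f"line {lineno}: marker id {marker!r} is not of the form chrom_pos"
        )
    try:
        return chrom, int(pos)
    except ValueError:
        raise BeagleFormatError(
            f"line {lineno}: marker id {marker!r} has a non-integer position"
        ) from None


def read_beagle(
    path,
    log10: bool = False,
    normalize: bool = False,
    sites=None,
) -> BeagleDataset:
    """Read a beagle genotype-likelihood file (plain or gzipped).

    Parameters
    ----------
    path :
        Beagle file with a header row; 3 + 3N columns per data row.
    log10 :
        Interpret GL columns as log10-scaled and convert to linear scale.
    normalize :
        Rescale each site/individual GL triple so its maximum is 1.
    sites :
        Optional ``(chrom_array, pos_array)`` overriding the coordinates
        parsed from marker ids (for ids that are not ``chrom_pos``).

    Raises
    ------
    BeagleFormatError
        On ragged rows, non-numeric likelihoods or unsorted positions; the
        message names the offending line.
    """
    markers, a1, a2, rows = [], [], [], []
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise BeagleFormatError("line 1: empty header")
        ncol = None
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1:
                parts = line.split()
            if not parts or parts == [""]:
                continue
            if ncol is None:
                ncol = len(parts)
                if ncol < 6 or (ncol - 3) % 3:
                    raise BeagleFormatError(
                        f"line {lineno}: expected 3 + 3N columns, got {ncol}"
                    )
            if len(parts) != ncol:
                raise BeagleFormatError(
                    f"line {lineno}: expected {ncol} columns, got {len(parts)}"
                )
            markers.append(parts[0])
            try:
                a1.append(_ALLELE_CODES[parts[1]])
                a2.append(_ALLELE_CODES[parts[2]])
            except KeyError:
                raise BeagleFormatError(
                    f"line {lineno}: unknown allele code in {parts[1:3]!r}"
                ) from None
            try:
                rows.append([float(v) for v in parts[3:]])
            except ValueError:
                raise BeagleFormatError(
                    f"line {lineno}: non-numeric genotype likelihood"
                ) from None
    if not rows:
        raise BeagleFormatError("no data rows")
    raw = np.asarray(rows)  # (L, 3N)
    n_ind = raw.shape[1] // 3
    gls = raw.reshape(raw.shape[0], n_ind, 3).transpose(1, 0, 2)
    if log10:
        gls = np.power(10.0, gls)
    if np.any(gls < 0):
        raise BeagleFormatError("negative genotype likelihoods (is the file log10-scaled?)")
    if normalize:
        m = gls.max(axis=2, keepdims=True)
        if np.any(m <= 0):
            raise BeagleFormatError("a site has an all-zero likelihood triple")
        gls = gls / m
    if sites is not None:
        chrom = np.asarray(sites[0])
        pos = np.asarray(sites[1], dtype=np.int64)
        if len(chrom) != len(markers) or len(pos) != len(markers):
            raise BeagleFormatError("sites override length does not match beagle rows")
    else:
        parsed = [_parse_marker(m, i + 2) for i, m in enumerate(markers)]
        chrom = np.asarray([c for c, _ in parsed])
        pos = np.asarray([p for _, p in parsed], dtype=np.int64)
    new_chrom = np.ones(len(pos), dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    bad = np.nonzero(~new_chrom & (np.diff(pos, prepend=pos[0] - 1) <= 0))[0]
    if bad.size:
        raise BeagleFormatError(
            f"line {bad[0] + 2}: positions not strictly increasing within chromosome"
        )
    return BeagleDataset(
        np.asarray(markers), np.asarray(a1, np.int8), np.asarray(a2, np.int8),
        np.ascontiguousarray(gls), chrom, pos,
    )


def write_beagle(path, dataset: BeagleDataset, precision: int = 6) -> None:
    """Write a beagle GL table (gzipped when the path ends in .gz)."""
    with _open_text(path, "wt") as fh:
        cols = ["marker", "allele1", "allele2"]
        for n in range(dataset.n_ind):
            cols += [f"Ind{n}"] * 3
        fh.write("\t".join(cols) + "\n")
        flat = dataset.gls.transpose(1, 0, 2).reshape(dataset.n_sites, -1)
        for l in range(dataset.n_sites):
            gl_txt = "\t".join(f"{v:.{precision}g}" for v in flat[l])
            fh.write(
                f"{dataset.markers[l]}\t{dataset.allele1[l]}\t{dataset.allele2[l]}\t{gl_txt}\n"
            )


def read_freqs(path, n_expected: int | None = None) -> np.ndarray:
    """Read a one-frequency-per-line file (allele1 frequencies, site order).

    ``n_expected`` (usually the beagle site count) is enforced when given.
    Values outside (0, 1) are allowed here — they are removed later by the
    MAF filter — but non-numeric lines are errors.
    """
    vals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                vals.append(float(s))
            except ValueError:
                raise BeagleFormatError(
                    f"line {lineno}: non-numeric frequency {s!r}"
                ) from None
    freqs = np.asarray(vals)
    if n_expected is not None and len(freqs) != n_expected:
        raise BeagleFormatError(
            f"frequency file has {len(freqs)} values but beagle has {n_expected} sites"
        )
    return freqs


def write_freqs(path, freqs, precision: int = 6) -> None:
    with _open_text(path, "wt") as fh:
        for f in np.asarray(freqs):
            fh.write(f"{f:.{precision}f}\n")


def filter_sites(freqs: np.ndarray, maf_min: float = 0.05) -> np.ndarray:
    """Indices of sites whose allele frequency lies in [maf_min, 1 - maf_min].

    With ``maf_min = 0`` this still drops fixed sites (frequency 0 or 1),
    which carry no relatedness information and break the HWE prior.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must lie in [0, 0.5), got {maf_min!r}")
    freqs = np.asarray(freqs, dtype=float)
    lo = max(maf_min, 0.0)
    keep = (freqs >= lo) & (freqs <= 1 - lo) & (freqs > 0) & (freqs < 1)
    return np.nonzero(keep)[0]


def thin_sites(positions, min_bp: int, chrom=None) -> np.ndarray:
    """Greedy distance thinning, an approximation to LD pruning.

    Scanning left to right within each chromosome, the first site is kept
    and a site is kept iff it lies at least ``min_bp`` beyond the last kept
    site.  Returns the retained indices.
    """
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    if chrom is None:
        chrom = np.zeros(n, dtype=np.int64)
    chrom = np.asarray(chrom)
    keep = np.zeros(n, dtype=bool)
    last_chrom = None
    last_pos = None
    for i in range(n):
        if chrom[i] != last_chrom:
            last_chrom = chrom[i]
            last_pos = None
        elif positions[i] <= last_pos:
            raise ValueError(f"positions not sorted at index {i}")
        if last_pos is None or positions[i] - last_pos >= min_bp:
            keep[i] = True
            last_pos = positions[i]
    return np.nonzero(keep)[0]


def estimate_freqs_em(
    dataset: BeagleDataset, tol: float = 1e-6, max_iter: int = 200
) -> np.ndarray:
    """EM estimate of allele1 frequencies from all individuals' GLs.

    Per site, iterate ``f <- (1/2N) sum_n sum_g g * w_n(g)`` with posterior
    genotype weights ``w_n(g) proportional to HWE(f)[g] * GL_n[g]`` until the
    largest frequency change drops below ``tol``.  Estimates are clamped to
    ``[1/(2N+2), 1 - 1/(2N+2)]`` (the usual pseudo-count bound, keeping them
    off the boundary).  Non-convergence after ``max_iter`` returns the last
    iterate.
    """
    gls = dataset.gls  # (N, L, 3)
    n_ind, n_sites, _ = gls.shape
    lo = 1.0 / (2 * n_ind + 2)
    f = np.full(n_sites, 0.5)
    g_vals = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        prior = genotype_prior(f)  # (L, 3)
        w = prior[None, :, :] * gls  # (N, L, 3)
        w_sum = w.sum(axis=2, keepdims=True)
        w = np.divide(w, w_sum, out=np.full_like(w, 1.0 / 3.0), where=w_sum > 0)
        f_new = (w @ g_vals).sum(axis=0) / (2 * n_ind)
        f_new = np.clip(f_new, lo, 1 - lo)
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            break
    return f


def read_genetic_map(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a 3-column genetic map: chrom, position (bp), cumulative cM.

    Returns a mapping chrom -> (positions, cumulative cM), each sorted by
    position.  Header lines whose third column is non-numeric are skipped.
    """
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise BeagleFormatError(f"line {lineno}: expected 3 columns")
            try:
                pos, cm = int(parts[1]), float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise BeagleFormatError(
                    f"line {lineno}: non-numeric map entry"
                ) from None
            per_chrom.setdefault(parts[0], []).append((pos, cm))
    out = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        cm = np.array([r[1] for r in rows])
        out[chrom] = (pos, cm)
    return out


def _interp_cm(pos: np.ndarray, map_pos: np.ndarray, map_cm: np.ndarray) -> np.ndarray:
    """Cumulative cM at ``pos`` by linear interpolation, extrapolating with
    the terminal interval slopes outside the mapped range."""
    cm = np.interp(pos, map_pos, map_cm)
    if len(map_pos) >= 2:
        left = pos < map_pos[0]
        right = pos > map_pos[-1]
        if left.any():
            slope = (map_cm[1] - map_cm[0]) / (map_pos[1] - map_pos[0])
            cm[left] = map_cm[0] + (pos[left] - map_pos[0]) * slope
        if right.any():
            slope = (map_cm[-1] - map_cm[-2]) / (map_pos[-1] - map_pos[-2])
            cm[right] = map_cm[-1] + (pos[right] - map_pos[-1]) * slope
    return cm


def genetic_distances(
    chrom, pos, cm_per_mb: float = 1.0, genetic_map=None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site genetic distance to the previous site, in Morgans.

    Either a constant ``cm_per_mb`` rate or a genetic map (see
    :func:`read_genetic_map`) converts physical gaps to genetic distance.
    Returns ``(dist_prev, new_chrom)``; the first site of each chromosome
    has distance 0 and ``new_chrom`` True (the HMM restarts there).
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    new_chrom = np.ones(n, dtype=bool)
    if n > 1:
        new_chrom[1:] = chrom[1:] != chrom[:-1]
    if genetic_map is None:
        cm = pos * (cm_per_mb / 1e6)
    else:
        cm = np.empty(n, dtype=float)
        for c in np.unique(chrom):
            m = chrom == c
            if str(c) not in genetic_map:
                raise KeyError(f"chromosome {c!r} missing from the genetic map")
            mp, mc = genetic_map[str(c)]
            cm[m] = _interp_cm(pos[m], mp, mc)
    dist = np.zeros(n)
    if n > 1:
        dist[1:] = np.maximum(cm[1:] - cm[:-1], 0.0) / 100.0  # cM -> Morgans
    dist[new_chrom] = 0.0
    return dist, new_chrom


def write_outputs(decode, segs, fit, prefix, sites: SiteTable, meta=None) -> dict:
    """Write the three result files and return their paths.

    ``{prefix}.sites.tsv``
        chrom, pos, Viterbi state, and the three posteriors (6 decimals).
    ``{prefix}.segments.bed``
        0-based half-open segments; columns 4-5 hold the IBD state and the
        mean posterior of that state.
    ``{prefix}.params.tsv``
        One data row: k0 k1 k2 alpha loglik nsites, preceded by ``#`` run
        metadata (package version plus caller-supplied key=value pairs).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": Path(str(prefix) + ".sites.tsv"),
        "segments": Path(str(prefix) + ".segments.bed"),
        "params": Path(str(prefix) + ".params.tsv"),
    }
    post = decode.posteriors
    vit = decode.viterbi_path
    n = len(sites)
    with open(paths["sites"], "w") as fh:
        fh.write("chrom\tpos\tviterbi\tpost0\tpost1\tpost2\n")
        for l in range(n):
            p0, p1, p2 = (post[l] if post is not None else (np.nan,) * 3)
            v = vit[l] if vit is not None else -1
            fh.write(
                f"{sites.chrom[l]}\t{sites.pos[l]}\t{v}\t{p0:.6f}\t{p1:.6f}\t{p2:.6f}\n"
            )
    with open(paths["segments"], "w") as fh:
        for s in segs:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{s.mean_posterior:.6f}\t{s.n_sites}\n"
            )
    with open(paths["params"], "w") as fh:
        fh.write(f"# ibdpair {__version__}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("k0\tk1\tk2\talpha\tloglik\tnsites\n")
        p = fit.params_hat
        fh.write(
            f"{p.k0:.6f}\t{p.k1:.6f}\t{p.k2:.6f}\t{p.alpha:.6g}\t{fit.loglik_hat:.6f}\t{n}\n"
        )
    return paths


def read_sites_tsv(path):
    """Read back a per-site output TSV -> (chrom, pos, viterbi, posteriors)."""
    chroms, pos, vit, post = [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.split("\t")
            chroms.append(parts[0])
            pos.append(int(parts[1]))
            vit.append(int(parts[2]))
            post.append([float(x) for x in parts[3:6]])
    return (
        np.asarray(chroms),
        np.asarray(pos, np.int64),
        np.asarray(vit, np.int8),
        np.asarray(post),
    )


def read_segments_bed(path) -> list[IBDSegment]:
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, st, mp, ns = line.split("\t")
            segs.append(
                IBDSegment(c, int(s), int(e), int(st), int(ns), float(mp))
            )
    return segs
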