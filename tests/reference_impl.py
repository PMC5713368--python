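"""Independent naive oracle for every descriptor kernel.

Deliberately written as direct per-position loops over letter strings and
property dictionaries, straight from the formula definitions, sharing no
code with the package kernels (which use pre-computed pair tables and
vectorized lookups).  Used by unit tests and the acceptance checks to
certify that the fast path changes nothing numerically.
"""

from __future__ import annotations

import itertools
import math


def norm_props(raw: dict[str, float]) -> dict[str, float]:
    values = list(raw.values())
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / len(values)
    std = math.sqrt(var)
    return {k: (v - mean) / std for k, v in raw.items()}


def all_tuples(alphabet: str, n: int) -> list[str]:
    return ["".join(p) for p in itertools.product(alphabet, repeat=n)]


def naive_kmer(seq: str, alphabet: str, k: int) -> list[float]:
    tuples = all_tuples(alphabet, k)
    total = len(seq) - k + 1
    counts = {t: 0 for t in tuples}
    for i in range(total):
        counts[seq[i : i + k]] += 1
    return [counts[t] / total for t in tuples]


def naive_kmer_collapsed(seq: str, alphabet: str, k: int, comp: dict[str, str]) -> list[float]:
    tuples = all_tuples(alphabet, k)
    def canon(t: str) -> str:
        rc = "".join(comp[c] for c in reversed(t))
        return min(t, rc, key=lambda x: tuple(alphabet.index(c) for c in x))
    classes = sorted({canon(t) for t in tuples},
                     key=lambda x: tuple(alphabet.index(c) for c in x))
    total = len(seq) - k + 1
    counts = {c: 0 for c in classes}
    for i in range(total):
        counts[canon(seq[i : i + k])] += 1
    return [counts[c] / total for c in classes]


def theta_matrix(norm_tables: list[dict[str, float]], a: str, b: str,
                 combine: str = "average") -> float:
    total = sum((h[a] - h[b]) ** 2 for h in norm_tables)
    return total / len(norm_tables) if combine == "average" else total


def naive_theta(seq: str, norm_tables: list[dict[str, float]], lam: int, n: int,
                combine: str = "average") -> list[float]:
    N = len(seq) - n + 1
    out = []
    for j in range(1, lam + 1):
        acc = 0.0
        for i in range(N - j):
            a = seq[i : i + n]
            b = seq[i + j : i + j + n]
            acc += theta_matrix(norm_tables, a, b, combine)
        out.append(acc / (N - j))
    return out


def naive_tau(seq: str, norm_tables: list[dict[str, float]], lam: int, n: int) -> list[float]:
    N = len(seq) - n + 1
    out = []
    for j in range(1, lam + 1):
        for h in norm_tables:
            acc = 0.0
            for i in range(N - j):
                acc += h[seq[i : i + n]] * h[seq[i + j : i + j + n]]
            out.append(acc / (N - j))
    return out


def naive_pse1(seq: str, alphabet: str, k: int, lam: int, omega: float,
               norm_tables: list[dict[str, float]], n: int) -> list[float]:
    freqs = naive_kmer(seq, alphabet, k)
    thetas = naive_theta(seq, norm_tables, lam, n)
    z = 1.0 + omega * sum(thetas)
    return [f / z for f in freqs] + [omega * t / z for t in thetas]


def naive_pse2(seq: str, alphabet: str, k: int, lam: int, omega: float,
               norm_tables: list[dict[str, float]], n: int) -> list[float]:
    freqs = naive_kmer(seq, alphabet, k)
    taus = naive_tau(seq, norm_tables, lam, n)
    z = 1.0 + omega * sum(taus)
    return [f / z for f in freqs] + [omega * t / z for t in taus]


def naive_one_hot(seq: str, alphabet: str, target_length: int) -> list[float]:
    out = [0.0] * (target_length * len(alphabet))
    for i, ch in enumerate(seq):
        out[i * len(alphabet) + alphabet.index(ch)] = 1.0
    return out


def _profiles(seq: str, norm_tables: list[dict[str, float]], n: int) -> list[list[float]]:
    N = len(seq) - n + 1
    return [[h[seq[i : i + n]] for i in range(N)] for h in norm_tables]


def naive_autocorrelation(seq: str, method: str, d_max: int,
                          norm_tables: list[dict[str, float]], n: int) -> list[float]:
    prof = _profiles(seq, norm_tables, n)
    N = len(prof[0])
    gamma = len(prof)
    means = [sum(p) / N for p in prof]

    def ac(v: int, w: int, d: int) -> float:
        return sum(
            (prof[v][i] - means[v]) * (prof[w][i + d] - means[w]) for i in range(N - d)
        ) / (N - d)

    out: list[float] = []
    if method in ("AC", "ACC"):
        for d in range(1, d_max + 1):
            out.extend(ac(v, v, d) for v in range(gamma))
    if method in ("CC", "ACC"):
        for d in range(1, d_max + 1):
            for v in range(gamma):
                for w in range(gamma):
                    if v != w:
                        out.append(ac(v, w, d))
    if method == "MORAN":
        for d in range(1, d_max + 1):
            for v in range(gamma):
                var = sum((x - means[v]) ** 2 for x in prof[v]) / N
                out.append(ac(v, v, d) / var if var > 0 else 0.0)
    if method == "GEARY":
        for d in range(1, d_max + 1):
            for v in range(gamma):
                var = sum((x - means[v]) ** 2 for x in prof[v]) / (N - 1)
                if var > 0:
                    num = sum(
                        (prof[v][i] - prof[v][i + d]) ** 2 for i in range(N - d)
                    ) / (2 * (N - d))
                    out.append(num / var)
                else:
                    out.append(0.0)
    if method == "NMBROTO":
        for d in range(1, d_max + 1):
            for v in range(gamma):
                out.append(
                    sum(prof[v][i] * prof[v][i + d] for i in range(N - d)) / (N - d)
                )
    return out


def naive_distance_pair(seq: str, alphabet: str, d_max: int) -> list[float]:
    size = len(alphabet)
    out = []
    for d in range(1, d_max + 1):
        counts = {(a, b): 0 for a in alphabet for b in alphabet}
        for i in range(len(seq) - d):
            counts[(seq[i], seq[i + d])] += 1
        for a in alphabet:
            for b in alphabet:
                out.append(counts[(a, b)] / (len(seq) - d))
    return out
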