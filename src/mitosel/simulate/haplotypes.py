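"""Intraspecific control-region haplotype sets with per-domain mutation rates.

Haplotypes are point-mutated copies of a reference CR (no indels, so the
set is trivially aligned).  Variability can be specified either as a
per-domain substitution rate or as an exact number of segregating sites
per domain; the truth record lists realized segregating sites per domain.
"""

from __future__ import annotations

import numpy as np

NUCS = "ACGT"


def simulate_cr_haplotypes(
    reference: str,
    domains: dict[str, tuple[int, int]],
    n: int,
    seed: int = 0,
    domain_rates: dict[str, float] | None = None,
    exact_sites: dict[str, int] | None = None,
) -> tuple[dict[str, str], dict]:
    """Generate n haplotypes from a reference CR.

    Exactly one of ``domain_rates`` (per-site, per-haplotype substitution
    probability) or ``exact_sites`` (planted segregating-site counts) must
    be given.  Returns ({name: sequence}, truth).
    """
    if (domain_rates is None) == (exact_sites is None):
        raise ValueError("supply exactly one of domain_rates or exact_sites")
    if n < 1:
        raise ValueError("need at least one haplotype")
    rng = np.random.default_rng(seed)
    ref = reference.upper()
    length = len(ref)
    for name, (s, e) in domains.items():
        if not (0 <= s < e <= length):
            raise ValueError(f"domain {name} [{s},{e}) outside reference")
    matrix = np.array([list(ref) for _ in range(n)], dtype="U1")

    if domain_rates is not None:
        for name, (s, e) in domains.items():
            rate = domain_rates.get(name, 0.0)
            if rate < 0:
                raise ValueError("rates must be >= 0")
            if rate == 0:
                continue
            mask = rng.random((n, e - s)) < rate
            for i, j in zip(*np.nonzero(mask)):
                col = s + j
                alternatives = [b for b in NUCS if b != matrix[i, col]]
                matrix[i, col] = alternatives[rng.integers(3)]
    else:
        if n < 2:
            raise ValueError("exact segregating sites require >= 2 haplotypes")
        for name, (s, e) in domains.items():
            k = exact_sites.get(name, 0)
            if k > e - s:
                raise ValueError(f"domain {name} too short for {k} sites")
            sites = rng.choice(np.arange(s, e), size=k, replace=False)
            for col in sites:
                alternatives = [b for b in NUCS if b != ref[col]]
                alt = alternatives[rng.integers(3)]
                n_carriers = int(rng.integers(1, n))  # proper non-empty subset
                carriers = rng.choice(n, size=n_carriers, replace=False)
                matrix[carriers, col] = alt

    haplotypes = {
        f"hap{i+1}": "".join(matrix[i]) for i in range(n)
    }
    segregating = {}
    for name, (s, e) in domains.items():
        seg = 0
        for col in range(s, e):
            if len(set(matrix[:, col])) >= 2:
                seg += 1
        segregating[name] = seg
    truth = {
        "seed": seed,
        "n": n,
        "domains": {k: list(v) for k, v in domains.items()},
        "segregating_sites": segregating,
        "mode": "rates" if domain_rates is not None else "exact",
    }
    return haplotypes, truth
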