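"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pytest


def nonwear_oracle_regex(cpm) -> list[tuple[int, int]]:
    """Independent non-wear oracle: maximal regex matches over a z/l/h alphabet.

    z = zero count, l = 1-199 cpm, h = >=200 cpm.  A non-wear bout is a
    maximal run of zeros in which low-count runs of at most 2 minutes are
    tolerated, with total length >= 60 and zero-count endpoints.
    """
    s = "".join("z" if c == 0 else ("l" if c <= 199 else "h") for c in cpm)
    out = []
    for m in re.finditer(r"z+(?:l{1,2}z+)*", s):
        if m.end() - m.start() >= 60:
            out.append((m.start(), m.end()))
    return out


def nonwear_oracle_bruteforce(cpm) -> list[tuple[int, int]]:
    """Exhaustive O(n^2) window scan; use only on short series."""
    cpm = list(cpm)
    n = len(cpm)
    valid = set()
    for i in range(n):
        if cpm[i] != 0:
            continue
        for j in range(i + 59, n):
            if cpm[j] != 0:
                continue
            win = cpm[i : j + 1]
            if any(c >= 200 for c in win):
                continue
            run, ok = 0, True
            for c in win:
                if c == 0:
                    run = 0
                else:
                    run += 1
                    if run > 2:
                        ok = False
                        break
            if ok:
                valid.add((i, j + 1))
    return sorted(
        iv for iv in valid
        if not any(a <= iv[0] and iv[1] <= b and (a, b) != iv for a, b in valid)
    )


def random_day(rng: np.random.Generator, n: int = 1440) -> np.ndarray:
    """A random minute series with sticky state runs so bouts actually occur."""
    cpm = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        state = rng.choice(["zero", "low", "active"], p=[0.45, 0.15, 0.40])
        length = int(rng.integers(1, 120))
        stop = min(i + length, n)
        if state == "zero":
            cpm[i:stop] = 0
        elif state == "low":
            cpm[i:stop] = rng.integers(1, 200, stop - i)
        else:
            cpm[i:stop] = rng.integers(200, 8000, stop - i)
        i = stop
    return cpm


def minute_frame(cpm, start="2022-03-07 00:00", pid="P0001") -> pd.DataFrame:
    """Wrap a cpm vector into the tidy counts frame the package consumes."""
    ts = pd.date_range(start, periods=len(cpm), freq="min")
    return pd.DataFrame({"participant_id": pid, "timestamp": ts, "cpm": np.asarray(cpm)})


@pytest.fixture
def rng():
    return np.random.default_rng(20220307)


@pytest.fixture(scope="session")
def small_study():
    """A small end-to-end study on the fast exposure path (session-cached)."""
    from actigut.compositional import ClrPolicy, clr_transform, prevalence_filter
    from actigut.synthetic import (
        SynthConfig, generate_covariates, generate_microbiome, generate_timeuse,
    )

    cfg = SynthConfig(
        n_participants=400, n_species=120, seed=11,
        effect_table=(("sp_0001", "MPA", 0.6), ("sp_0002", "SED", -0.5)),
    )
    cov = generate_covariates(cfg)
    timeuse = generate_timeuse(cfg)
    exposures = timeuse[["z_alr_SED", "z_alr_MPA", "z_alr_VPA"]]
    species, genes = generate_microbiome(cfg, exposures, cov)
    kept, _ = prevalence_filter(species)
    clr = clr_transform(kept, ClrPolicy.species())
    covariates = pd.concat([cov, timeuse[["wear_minutes", "pct_weekend_wear"]]], axis=1)
    return {"config": cfg, "covariates": covariates, "timeuse": timeuse,
            "exposures": exposures, "species": species, "genes": genes, "clr": clr}
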