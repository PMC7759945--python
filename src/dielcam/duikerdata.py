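"""Published summary counts from a multi-site camera-trap survey of six
duiker species in Central African rainforests.

These are the community's reported tallies — independent detection events
per site and species, per-species day/night/twilight splits, and the
deployment/retention station counts — shipped as package data the way R
analysis packages bundle worked-example datasets.  They parameterise the
study replica in :mod:`dielcam.simulate` and drive the worked examples.
"""

from __future__ import annotations

import pandas as pd

from ._util import as_rng

SPECIES = [
    "C. callipygus",
    "C. castaneus",
    "C. leucogaster",
    "C. nigrifrons",
    "C. silvicultor",
    "P. congica",
]

#: independent detection events per site (rows) and species (columns)
SITE_SPECIES_EVENTS: dict[str, tuple[int, ...]] = {
    "Dja CMR": (70, 30, 0, 1, 60, 417),
    "Makalaya CMR": (140, 30, 1, 1, 32, 151),
    "Mindourou 1 CMR": (7, 13, 0, 0, 6, 42),
    "Mindourou 2 CMR": (27, 17, 0, 1, 14, 99),
    "Mindourou 3 CMR": (12, 13, 0, 0, 4, 86),
    "Ingolo COG": (1, 35, 0, 0, 10, 113),
    "Ngombe COG": (230, 148, 1, 0, 55, 545),
    "Bambidie GBN": (100, 45, 12, 1, 14, 52),
    "Djoutou GBN": (102, 31, 19, 3, 19, 359),
    "Ndambie GBN": (116, 67, 25, 0, 30, 77),
    "Ovan GBN": (140, 36, 3, 8, 35, 601),
    "Maduda RDC": (0, 4, 0, 27, 0, 20),
}

#: per-species (n_total, n_in_principal_period, n_twilight); the principal
#: period is daylight for the diurnal species and night for the nocturnal
#: ones (C. castaneus, C. silvicultor)
DIEL_COUNTS: dict[str, tuple[int, int, int]] = {
    "C. callipygus": (945, 816, 278),
    "C. castaneus": (469, 465, 51),
    "C. leucogaster": (61, 55, 13),
    "C. nigrifrons": (42, 33, 10),
    "C. silvicultor": (279, 236, 59),
    "P. congica": (2562, 2474, 666),
}

NOCTURNAL_SPECIES = ("C. castaneus", "C. silvicultor")

STATIONS_DEPLOYED = 428
STATIONS_RETAINED = 315
TRAP_NIGHTS = 17827

#: excluded from pairwise analyses: occupies a distinct (swampy) habitat
EXCLUDED_FROM_PAIRWISE = ("C. nigrifrons",)


def site_species_table() -> pd.DataFrame:
    """The site x species event-count table as a DataFrame."""
    return pd.DataFrame.from_dict(SITE_SPECIES_EVENTS, orient="index", columns=SPECIES)


def events_from_counts(
    counts: pd.DataFrame | None = None,
    seed=0,
    stations_per_site: int = 6,
    burst_fraction: float = 0.15,
) -> pd.DataFrame:
    """Materialise a detection-record table whose independent-event counts
    match a site x species count table exactly.

    Events are laid out >= 2 h apart within each (station, species), so the
    1-h independence rule retains all of them; a ``burst_fraction`` of
    events additionally spawns a duplicate photo within the hour, which the
    filter must discard.  Useful for exercising the ingest stage against a
    known census.
    """
    counts = site_species_table() if counts is None else counts
    rng = as_rng(seed)
    rows = []
    base = pd.Timestamp("2017-01-01 00:00")
    for site, row in counts.iterrows():
        for species, k in row.items():
            k = int(k)
            if k == 0:
                continue
            stations = [f"{site}#{i + 1:02d}" for i in range(stations_per_site)]
            for e in range(k):
                st = stations[e % stations_per_site]
                slot = e // stations_per_site
                # 2-h spacing within a station; minute jitter keeps times varied
                ts = base + pd.Timedelta(hours=2 * slot, minutes=int(rng.integers(0, 50)))
                rows.append((site, st, species, ts, 1))
                if rng.uniform() < burst_fraction:
                    rows.append((site, st, species, ts + pd.Timedelta(minutes=int(rng.integers(1, 45))), 1))
    df = pd.DataFrame(rows, columns=["site", "station", "species", "datetime", "count"])
    return df.sort_values(["site", "station", "species", "datetime"]).reset_index(drop=True)
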