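"""Independence filtering and diel classification on the published census.

Builds a raw detection-record table whose per-site/species event counts
match the published survey census (plus injected sub-hour photo bursts),
runs the 1-hour independence filter, and classifies each species' events
against the 06:00/18:00 solar schedule.
"""

from dielcam import duikerdata
from dielcam.events import DielSummary, filter_independent_events

records = duikerdata.events_from_counts(seed=1)
events = filter_independent_events(records, window_minutes=60)

print(f"raw photo records : {len(records)}")
print(f"independent events: {len(events)}  (bursts within 1 h collapsed)")
print()
print("events per species:")
print(events.groupby("species").size().to_string())
print()
print("diel classification from the published day/night tallies:")
for sp, (n_total, n_principal, n_twi) in duikerdata.DIEL_COUNTS.items():
    nocturnal = sp in duikerdata.NOCTURNAL_SPECIES
    kw = {"n_nocturnal" if nocturnal else "n_diurnal": n_principal}
    s = DielSummary.from_counts(sp, n_total, n_twilight=n_twi, **kw)
    pct = s.pct_nocturnal if nocturnal else s.pct_diurnal
    period = "nocturnal" if nocturnal else "diurnal"
    print(f"  {sp:16s} {pct:3.0f}% {period:9s} twilight {s.pct_twilight:3.0f}%  -> {s.category}")
print()
print("'category' applies the 10/30/70/90% nocturnal-fraction bands; the")
print("event counts above reproduce the census exactly because every layout")
print("event is spaced beyond the 1-h window while injected bursts are not.")
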