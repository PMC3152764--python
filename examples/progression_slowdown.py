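"""The treatment mechanism: a disease-progression clock slowdown.

While a patient is on preventive therapy with effectiveness e, their disease
clock advances at rate 1 - e; off therapy it runs at rate 1.  This script
walks the canonical worked example: a patient two years from AD onset on a
50%-effective drug.
"""

from adscreensim import apply_progression_slowdown

onset, start = 72.0, 70.0

for years_on_therapy in (1.0, 2.0, 4.0):
    delayed = apply_progression_slowdown(onset, start, start + years_on_therapy, 0.5)
    print(
        f"{years_on_therapy:.0f}y of therapy: onset {onset:.0f} -> {delayed:.2f} "
        f"(delay {delayed - onset:.2f}y)"
    )

unending = apply_progression_slowdown(onset, start, None, 0.5)
print(f"therapy until onset: onset {onset:.0f} -> {unending:.2f} (delay {unending - onset:.2f}y)")

# Reading: 2 years of 50%-effective therapy buy 1 extra pre-AD year; staying
# on therapy until onset doubles the remaining time (the t/2 + t/4 + ... -> t
# geometric limit), so the maximum delay here is 2 years.
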