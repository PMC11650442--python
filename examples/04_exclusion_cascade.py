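"""Apply the exclusion cascade to the built-in toy cohort.

The 12-participant toy fixture contains exactly one violator of each
exclusion rule; the cascade excludes each at its first failing step and
reports an audit row per step.
"""

import swedgi as sg
from swedgi.filters import audit_frame

toy = sg.make_toy_fixture()
print(f"toy cohort: {toy.n} participants "
      f"({len(toy.diet)} diet rows, {toy.abundance.n_samples} metagenomic samples)")
print()

steps = sg.MICROBIOME_CASCADE + ("antibiotics",)
kept, audit = sg.apply_exclusions(toy, steps)
print(audit_frame(audit).to_string(index=False))
print()
print(f"analysis sample: {kept.n} participants -> {sorted(kept.pids)}")
print("Each audit row excludes exactly one participant; n_before - n_excluded")
print("= n_after at every step, so the audit reconciles input and output n.")
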