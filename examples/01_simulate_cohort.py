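"""Generate a synthetic linked primary/secondary-care cohort.

The generator plants RA signal (diagnosis codes, DMARD dose variants sharing
a code prefix, a psoriatic-arthritis exclusion code) among uninformative
noise codes, and withholds the gold-standard label from unlinked patients.
"""

from codephen import RA, SimulationConfig, simulate

config = SimulationConfig(seed=1)  # 2,000 patients, 17% prevalence, 80% linked
events, labels, truth = simulate(config)

n_cases = sum(1 for v in truth.latent_labels.values() if v == RA)
print(f"patients:          {config.n_patients}")
print(f"coded events:      {len(events)}")
print(f"latent RA cases:   {n_cases} ({100 * n_cases / config.n_patients:.1f}%)")
print(f"linked (labelled): {len(labels)} ({100 * len(labels) / config.n_patients:.1f}%)")
print(f"first event:       {events[0]}")
# The labelled subset is what every supervised phase sees; the latent labels
# of unlinked patients exist only in `truth`, for validating scenario bounds.
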