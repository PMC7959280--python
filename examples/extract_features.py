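"""Extract the 60-feature table from a small simulated dataset.

Each gesture epoch becomes one row: 54 scoped network features (6 families
x 3 cortices x left/right/whole), 3 whole-brain graph features, and 3
cortex power features, plus the gesture label and hand.
"""

import gesturenet as gn

config, montage = gn.gesture_simulation_config(
    hand="non-dominant", n_per_class=3, coupling=0.9, seed=3)
recording, annotations = gn.generate_dataset(config)
epochs = gn.extract_epochs(recording, annotations)

table = gn.extract_feature_table(
    epochs, montage,
    comm_config=gn.CommunityConfig(repetitions=20, null_permutations=20),
    seed=3)

print(f"{len(table)} epochs x {len(gn.feature_names())} features")
show = ["flexibility.motor.left", "recruitment.motor.whole",
        "strength.cognition.whole", "global_efficiency", "power.motor"]
print(table[show + ["label"]].round(3).to_string(index=False))
# Flexibility near 0 means stable communities within the epoch; recruitment
# near 1 means a cortex's channels stay in one community; strength and
# power track the planted coupling and per-class amplitude gain.
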