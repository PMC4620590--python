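ascending_stairs: ascending_stairs.csv
descending_stairs: descending_stairs.csv
knee_bending: knee_bending.csv
sitting_down: sitting_down.csv
standing: standing.csv
standing_up: standing_up.csv
walking: walking.csv
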