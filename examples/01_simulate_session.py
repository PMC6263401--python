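"""Generate one synthetic multimodal session and write it to disk.

The session carries EEG (Fz, Pz), ECG, vertical EOG at 500 Hz, a pupil
trace at 60 Hz and six NIRS streams at 10.2 Hz, plus the baseline/encoding
window map and the latent engagement state of every encoding window.
"""

import numpy as np

import engage_fuse as ef

cfg = ef.SimulationConfig(n_participants=1, n_trials=12, seed=42)
session = ef.generate_session(cfg, "P01")

print(f"participant {session.participant_id}: {session.duration_s:.0f} s recording")
print(f"{len(session.encoding_windows)} encoding windows of "
      f"{session.encoding_windows[0].duration_s:.0f} s after a "
      f"{session.baseline_window.duration_s:.0f} s neutral baseline")
print("latent states:", " ".join(session.latent_states))
for name in ("eeg_fz", "ecg", "eog", "pupil", "nirs_oxy_fp1"):
    st = session.streams[name]
    print(f"  {name:13s} {len(st.samples):7d} samples @ {st.fs:5.1f} Hz")

# the tracker loses the pupil during every blink
gaps = np.isnan(session.streams["pupil"].samples).sum()
print(f"pupil samples blanked by blinks: {gaps}")

files = ef.write_session(session, "scratch/example_session")
print(f"wrote {len(files)} files; read_session() restores them bit-identically")
assert ef.read_session("scratch/example_session") == session
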