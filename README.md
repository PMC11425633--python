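# deglutio

Offline pipeline for automated swallowing-status assessment from a wearable
dual-channel surface-EMG + neck-microphone patch, built to run entirely on
physiology-shaped **synthetic** data (no hardware, no downloads):

1. **simulate** — generates annotated multimodal sessions at 2 kHz: sequential
   digastric/sternohyoid EMG bursts synchronized with the three swallowing
   sound waves for normal swallows of three consistencies, a desynchronized
   and prolonged pattern for silent aspiration, plus cough, chewing and rest.
2. **signalproc** — zero-phase 20–100 Hz EMG bandpass with a 59–61 Hz notch,
   10–900 Hz sound bandpass with optional spectral-subtraction noise
   reduction, polyphase resampling to the 250 Hz model rate, STFT
   spectrograms, and amplitude-ratio SNR (`20·log10(A_signal/A_noise)`).
3. **dataset** — 2-s, 3-channel epochs normalized to [0, 1], +0.2 s shift
   augmentation with majority-overlap relabeling, and participant-disjoint
   60:20:20 train/validation/test splits.
4. **classifier** — a CNN-BiLSTM written in pure NumPy (hand-derived
   backprop; no deep-learning framework needed): three conv blocks
   (80/48/112 filters with kernels 5/3/3, each followed by a 16-filter
   kernel-4 conv, batch norm, PReLU, max-pool 2), a 10-unit bidirectional
   LSTM, dense layers of 140/512/256 units with 0.2 dropout after the
   second, softmax over 7 classes, trained with Adam (lr 0.001) on
   categorical cross-entropy, checkpointing on validation accuracy.
5. **evaluation** — 7×7 confusion matrix with accuracy and one-vs-rest
   sensitivity/specificity, the 6 dB SNR electrode-placement check, and
   session reports that flag silent-aspiration events.
6. **interface** — YAML config, TSV/WAV recording I/O, and a CLI chaining
   the whole thing.

Classes: `rest, liquid, soft_food, dense_food, silent_aspiration, cough,
chewing` (this ordering is fixed throughout: one-hot vectors, confusion
matrices, model outputs).

## CLI

```bash
deglutio simulate --participants 5 --events 6 --seed 1 --out raw/
deglutio preprocess --in raw/ --out pre/
deglutio dataset --in pre/ --augment-shifts 2 --seed 1 --out data.npz
deglutio train --data data.npz --seed 1 --out model.npz
deglutio classify --model model.npz --in pre/P001.tsv --out timeline.json
deglutio report --model model.npz --in pre/P001.tsv --out report/
deglutio placement-check --in raw/P001.tsv
deglutio run-all --seed 1 --out pipeline_out/   # full chain in one shot
```

Recordings are plain TSV (time + emg1 + emg2 + sound, with `# fs_hz=` /
`# participant_id=` headers) plus a `<stem>.annotations.tsv` sidecar of
`start_s  end_s  label` rows; the sound channel can be mirrored to 16-bit
PCM WAV.

## Notes

- All simulator timing/amplitude constants are invented, documented defaults
  (the source physiology is qualitative); they are chosen so classes are
  separable but non-trivially so.
- A 10–900 Hz sound passband cannot survive resampling to 250 Hz
  (Nyquist 125 Hz); the chain filters at the acquisition rate first and
  accepts the loss of content above 125 Hz during decimation.
- Everything is deterministic given the seed, including network
  initialization, batching, dropout and the dataset split.
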