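# Transcribing the full curated DDR network

The complete curated model of the DNA damage response (96 regulatory
components connected by 98 interactions, with ternary ATM-P,
IKK-complex-P and IκBα) is distributed as supplementary material of the
original study and is not bundled with this package.

To run the full-network analyses:

1. Transcribe the published function list into the native JSON format
   (see core_model.json / ddr_synthetic_subnetwork.json for the shape):
   one term per interaction, keeping the published interaction numbers as
   term ids and the published time-scale values as "time_scale".
2. Record basal activities as "default_level" (IκBα: 2, IKK-complex-P: 1;
   everything else 0 unless the function list says otherwise).
3. Transcribe the two exclusion lists into
   excluded_sensitization_targets.txt and excluded_defect_targets.txt
   (one component name per line; '#' starts a comment).
4. Load with  lddr.ddr.load_full_model(path)  — the loader checks the
   component census, the interaction count, and the ternary set, and
   reports any mismatch.
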