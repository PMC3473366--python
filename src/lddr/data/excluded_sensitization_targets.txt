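# Components excluded from sensitization-target searches (template).
# One component name per line.  Populate from the published exclusion
# list when working with the transcribed full network; the entry below
# is the package's own default (lesions are not drug targets).
DSBs_late
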