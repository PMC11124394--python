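# Gene symbol -> beta-tubulin isotype label, editable.
# Unmapped genes in an expression file are ignored with a warning.
TUBB=βI
TUBB2A=βIIa
TUBB2B=βIIb
TUBB3=βIII
TUBB4=βIVa
TUBB2C=βIVb
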