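level,median,q1,q3,min,max,provenance
no_access,1.4,0.5,5.0,0.0,36.9,"State-level summary, overall population"
below_average,23.5,15.4,36.2,2.1,90.9,"State-level summary, overall population"
average,38.9,26.9,54.2,4.9,79.0,"State-level summary, overall population"
above_average,23.3,6.0,45.5,0.0,72.3,"State-level summary, overall population"
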