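taxon,reliance,trend,lo,hi,endemic
menzbieri bar-tailed godwit,1.00,-0.061,-0.087,-0.037,1
far eastern curlew,0.95,-0.058,-0.070,-0.046,1
curlew sandpiper,0.90,-0.075,-0.095,-0.055,0
great knot,0.90,-0.051,-0.075,-0.025,1
red knot,0.90,-0.044,-0.066,-0.022,0
lesser sand plover,0.70,-0.060,-0.102,-0.020,0
baueri bar-tailed godwit,0.50,-0.014,-0.022,-0.006,1
terek sandpiper,0.40,-0.023,-0.067,0.020,0
red-necked stint,0.35,-0.016,-0.031,0.000,1
grey-tailed tattler,0.03,0.011,-0.021,0.041,1
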