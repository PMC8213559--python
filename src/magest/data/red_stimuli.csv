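stimulus,nominal_pct,X,Y,Z,L_star,h_star,S,is_reference
Red 15%,15,63.00,61.80,58.83,82.81,36.54,14.97,0
Red 25%,25,65.86,61.35,53.62,82.56,34.30,24.98,0
Red 35%,35,70.32,62.11,48.68,82.97,34.66,35.14,0
Red 45%,45,74.07,61.51,43.66,82.65,32.91,44.95,0
Red 50%,50,76.56,61.72,40.56,82.76,33.72,49.79,1
Red 55%,55,79.54,61.89,37.18,82.56,34.21,54.96,0
Red 65%,65,86.91,61.82,30.84,82.82,33.33,65.11,0
Red 75%,75,97.81,61.90,22.69,82.86,33.41,75.10,0
Red 85%,85,117.35,61.79,11.61,82.80,34.34,85.04,0
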