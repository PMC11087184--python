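component,segment,border,control_mean,control_sd,HFpEF_mean,HFpEF_sd,HFmrEF_mean,HFmrEF_sd,HFrEF_mean,HFrEF_sd
overall,1,epi,11.3,2.5,8.3,3.0,8.6,2.9,8.2,2.9
overall,1,endo,12.2,3.0,9.4,3.1,9.1,3.2,8.5,3.1
overall,2,epi,7.9,2.4,6.6,2.0,6.2,2.0,6.0,2.0
overall,2,endo,6.9,1.9,5.9,1.6,5.7,1.6,5.7,1.7
overall,3,epi,8.6,2.5,6.7,2.3,6.2,2.3,5.8,2.3
overall,3,endo,8.3,2.3,6.5,2.1,6.2,2.1,5.9,2.4
overall,4,epi,12.6,3.4,10.2,3.6,10.3,3.4,8.3,2.8
overall,4,endo,12.3,2.9,10.3,3.4,10.0,3.3,8.6,2.7
overall,5,epi,12.8,2.5,12.1,3.3,11.3,3.4,9.9,2.9
overall,5,endo,13.2,2.7,12.3,3.1,11.1,3.6,10.0,3.0
overall,6,epi,13.4,3.1,12.0,3.4,11.6,3.6,10.4,3.3
overall,6,endo,13.8,3.0,12.7,3.3,12.1,3.4,10.6,3.4
overall,7,epi,6.9,1.7,5.6,2.1,5.4,2.1,5.8,2.3
overall,7,endo,9.5,2.4,8.8,2.7,7.2,2.6,6.3,2.7
overall,8,epi,5.2,1.5,4.9,1.3,4.5,1.7,4.8,1.6
overall,8,endo,7.8,1.8,7.4,2.0,6.0,2.0,5.2,2.0
overall,9,epi,5.8,1.7,5.1,1.8,4.7,1.7,4.7,1.8
overall,9,endo,7.7,1.7,7.1,2.1,5.8,1.7,5.2,2.0
overall,10,epi,9.3,2.5,8.0,2.9,8.1,2.7,6.9,2.2
overall,10,endo,10.1,1.8,9.2,2.5,8.3,2.4,7.0,2.3
overall,11,epi,9.6,1.8,10.0,2.9,9.4,2.9,8.5,3.0
overall,11,endo,10.1,2.0,10.4,2.7,9.3,3.0,8.8,3.3
overall,12,epi,10.0,2.6,9.6,3.1,9.6,3.2,9.1,3.3
overall,12,endo,10.0,2.3,10.0,2.6,9.6,2.9,9.0,3.3
overall,13,epi,4.5,1.2,4.8,1.5,4.2,1.3,4.3,1.7
overall,13,endo,7.7,1.9,7.9,2.0,6.1,1.8,5.1,2.1
overall,14,epi,4.8,0.9,5.4,1.3,4.7,1.3,4.5,1.4
overall,14,endo,8.2,1.8,8.6,1.9,6.7,1.6,5.3,1.7
overall,15,epi,6.7,1.5,6.6,2.1,6.2,1.7,5.6,1.8
overall,15,endo,9.4,2.1,9.6,2.1,7.7,2.2,6.2,2.0
overall,16,epi,7.0,1.4,7.7,2.1,7.2,2.3,7.0,2.7
overall,16,endo,8.1,1.6,8.6,1.9,7.8,2.0,7.2,2.5
overall,17,epi,5.6,1.3,6.2,1.5,5.5,1.5,5.1,1.6
longitudinal,1,epi,6.4,2.0,4.2,1.7,4.6,2.0,4.8,2.1
longitudinal,1,endo,5.2,1.7,4.0,1.3,4.3,1.8,4.3,2.1
longitudinal,2,epi,7.4,2.3,5.9,2.0,5.6,1.8,5.3,1.9
longitudinal,2,endo,4.9,1.8,3.8,1.5,4.0,1.5,4.3,1.4
longitudinal,3,epi,7.1,2.3,5.7,2.3,5.0,1.9,4.8,2.2
longitudinal,3,endo,6.7,2.1,5.0,2.1,5.0,2.1,4.8,2.2
longitudinal,4,epi,9.8,2.9,7.6,2.8,7.7,2.8,6.5,2.5
longitudinal,4,endo,8.5,2.7,6.8,2.8,7.1,2.8,6.4,2.5
longitudinal,5,epi,9.9,2.2,8.3,2.6,8.2,2.9,7.3,2.4
longitudinal,5,endo,9.1,2.5,7.2,2.1,7.1,2.8,6.8,2.5
longitudinal,6,epi,9.7,2.8,7.5,2.8,7.9,2.9,7.6,2.7
longitudinal,6,endo,8.4,2.7,6.1,2.2,7.1,2.9,6.9,2.7
longitudinal,7,epi,5.6,1.8,4.3,1.8,4.6,2.0,5.2,2.4
longitudinal,7,endo,3.7,1.4,3.8,1.5,3.7,1.9,4.5,2.5
longitudinal,8,epi,4.5,1.6,3.8,1.3,3.7,1.5,3.7,1.4
longitudinal,8,endo,4.0,1.1,4.3,1.4,3.3,1.3,3.0,0.9
longitudinal,9,epi,4.4,1.7,3.7,1.7,3.6,1.6,3.6,1.6
longitudinal,9,endo,3.5,1.0,3.7,1.3,3.0,1.1,3.2,1.4
longitudinal,10,epi,8.4,2.7,6.8,3.1,7.3,2.9,6.1,2.4
longitudinal,10,endo,6.3,2.3,5.4,2.2,5.8,2.7,5.6,2.5
longitudinal,11,epi,8.6,2.1,8.6,2.9,8.2,3.1,7.7,3.0
longitudinal,11,endo,7.4,2.5,7.0,2.1,6.8,3.0,7.3,3.2
longitudinal,12,epi,9.0,2.7,8.1,3.4,8.4,3.4,8.3,3.3
longitudinal,12,endo,6.8,2.5,6.2,2.2,6.9,3.1,7.3,3.3
longitudinal,13,epi,3.9,1.4,4.2,1.5,3.7,1.2,3.9,1.6
longitudinal,13,endo,4.2,1.5,4.6,1.6,3.8,1.5,3.9,1.9
longitudinal,14,epi,3.6,0.9,4.2,1.2,3.7,1.2,3.4,0.9
longitudinal,14,endo,4.9,1.5,5.6,1.7,4.5,1.5,3.6,1.3
longitudinal,15,epi,4.9,1.7,4.3,2.0,4.7,2.0,4.3,1.8
longitudinal,15,endo,4.2,1.3,4.9,1.4,4.0,1.4,4.0,1.9
longitudinal,16,epi,5.7,1.4,6.2,2.1,6.2,2.4,6.4,2.7
longitudinal,16,endo,5.1,1.3,5.5,1.4,5.5,2.0,6.0,2.7
longitudinal,17,epi,4.5,1.0,5.1,1.3,4.6,1.4,4.5,1.5
radial,1,epi,9.2,2.0,7.3,2.6,7.3,2.3,6.6,2.1
radial,1,endo,10.8,2.9,8.5,3.0,8.1,3.0,7.4,2.7
radial,2,epi,3.9,1.2,3.5,1.2,3.3,1.5,3.5,1.6
radial,2,endo,5.5,1.5,4.9,1.3,4.6,1.3,4.3,1.6
radial,3,epi,5.2,1.3,4.0,1.4,3.9,1.6,3.7,1.4
radial,3,endo,5.3,1.8,4.7,1.4,4.0,1.4,3.9,1.8
radial,4,epi,7.5,1.9,6.6,2.1,6.3,2.0,4.9,1.5
radial,4,endo,9.1,2.1,8.0,2.4,7.2,2.2,5.8,1.8
radial,5,epi,7.7,1.5,8.7,2.4,7.5,2.1,6.6,1.9
radial,5,endo,9.8,1.9,10.4,2.7,8.6,2.9,7.5,2.4
radial,6,epi,9.0,2.0,9.4,2.3,8.4,2.3,7.3,2.1
radial,6,endo,11.3,2.4,11.4,2.9,10.0,2.6,8.4,2.7
radial,7,epi,4.4,1.2,4.0,1.6,3.5,1.4,3.1,1.2
radial,7,endo,9.0,2.4,8.2,2.6,6.5,2.4,4.8,2.0
radial,8,epi,3.8,1.2,3.6,1.1,3.2,1.4,3.5,1.5
radial,8,endo,7.2,1.9,6.5,2.1,5.3,2.0,4.5,2.1
radial,9,epi,4.0,1.2,3.9,1.4,3.4,1.3,3.4,1.5
radial,9,endo,7.1,1.6,6.4,2.0,5.2,1.6,4.4,1.8
radial,10,epi,4.4,1.2,4.5,1.6,3.9,1.5,3.4,1.6
radial,10,endo,8.1,1.6,7.8,2.2,6.1,1.5,4.6,1.8
radial,11,epi,4.6,1.2,5.3,1.7,4.6,1.7,4.1,1.6
radial,11,endo,7.1,1.7,8.3,2.3,6.5,2.1,5.2,2.1
radial,12,epi,4.6,1.6,5.5,1.5,4.7,1.5,4.2,1.8
radial,12,endo,7.6,2.0,8.3,2.2,6.8,1.8,5.6,2.1
radial,13,epi,2.8,0.9,2.9,1.1,2.5,1.2,2.2,1.1
radial,13,endo,6.8,2.1,6.9,2.1,5.2,1.8,3.7,1.8
radial,14,epi,3.6,1.0,4.0,1.2,3.3,1.2,3.2,1.5
radial,14,endo,7.1,1.7,7.0,2.0,5.4,1.8,4.3,1.8
radial,15,epi,5.0,1.3,5.2,1.9,4.5,1.6,4.1,1.9
radial,15,endo,8.8,2.1,8.7,2.1,6.9,2.3,5.2,2.1
radial,16,epi,4.4,1.4,5.0,1.5,4.2,1.7,3.4,1.4
radial,16,endo,7.0,1.7,7.5,1.8,6.1,1.8,4.6,1.6
radial,17,epi,3.8,1.2,4.1,1.3,3.4,1.2,2.8,1.1
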