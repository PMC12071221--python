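weekday,name,count
1,Monday,7125
2,Tuesday,6959
3,Wednesday,6599
4,Thursday,6833
5,Friday,6812
6,Saturday,6973
7,Sunday,6734
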