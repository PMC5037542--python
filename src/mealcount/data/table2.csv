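rater,method,day,session,meal,t_pre_s,t_post_s,t_entry_s
1,MCM,1,1,dinner,156,129,198
2,TM,1,1,dinner,436,154,946
3,TM,1,1,dinner,517,72,966
4,MCM,1,1,dinner,228,101,209
1,TM,1,2,lunch,498,89,906
2,MCM,1,2,lunch,174,142,160
3,MCM,1,2,lunch,186,184,179
4,MCM,1,2,lunch,411,274,828
1,MCM,2,1,breakfast,120,120,180
2,MCM,2,1,breakfast,84,101,178
3,TM,2,1,breakfast,420,180,740
4,TM,2,1,breakfast,312,108,780
1,TM,2,2,lunch,396,174,792
2,TM,2,2,lunch,468,234,852
3,MCM,2,2,lunch,138,108,246
4,MCM,2,2,lunch,150,174,162
1,TM,3,1,breakfast,96,132,186
2,MCM,3,1,breakfast,420,159,660
3,TM,3,1,breakfast,91,112,203
4,MCM,3,1,breakfast,374,122,726
1,TM,3,2,dinner,547,172,1049
2,MCM,3,2,dinner,208,121,259
3,TM,3,2,dinner,547,142,968
4,MCM,3,2,dinner,189,101,199
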