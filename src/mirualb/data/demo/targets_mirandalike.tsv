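miR-t0	GENE000	mirandalike
miR-t0	GENE004	mirandalike
miR-t0	GENE011	mirandalike
miR-t0	GENE012	mirandalike
miR-t0	GENE018	mirandalike
miR-t0	GENE024	mirandalike
miR-t0	GENE025	mirandalike
miR-t0	GENE027	mirandalike
miR-t0	GENE029	mirandalike
miR-t0	GENE033	mirandalike
miR-t0	GENE044	mirandalike
miR-t0	GENE045	mirandalike
miR-t0	GENE046	mirandalike
miR-t0	GENE048	mirandalike
miR-t0	GENE054	mirandalike
miR-t0	GENE063	mirandalike
miR-t0	GENE069	mirandalike
miR-t0	GENE071	mirandalike
miR-t0	GENE074	mirandalike
miR-t0	GENE075	mirandalike
miR-t0	GENE076	mirandalike
miR-t0	GENE079	mirandalike
miR-t0	GENE081	mirandalike
miR-t1	GENE003	mirandalike
miR-t1	GENE004	mirandalike
miR-t1	GENE013	mirandalike
miR-t1	GENE042	mirandalike
miR-t1	GENE046	mirandalike
miR-t1	GENE050	mirandalike
miR-t1	GENE096	mirandalike
miR-t2	GENE001	mirandalike
miR-t2	GENE009	mirandalike
miR-t2	GENE018	mirandalike
miR-t2	GENE023	mirandalike
miR-t2	GENE034	mirandalike
miR-t2	GENE045	mirandalike
miR-t2	GENE068	mirandalike
miR-t2	GENE088	mirandalike
miR-t2	GENE093	mirandalike
miR-t2	GENE094	mirandalike
miR-t3	GENE004	mirandalike
miR-t3	GENE008	mirandalike
miR-t3	GENE016	mirandalike
miR-t3	GENE023	mirandalike
miR-t3	GENE024	mirandalike
miR-t3	GENE045	mirandalike
miR-t3	GENE054	mirandalike
miR-t3	GENE060	mirandalike
miR-t3	GENE065	mirandalike
miR-t3	GENE071	mirandalike
miR-t3	GENE077	mirandalike
miR-t3	GENE083	mirandalike
miR-t3	GENE085	mirandalike
miR-t3	GENE091	mirandalike
miR-t3	GENE096	mirandalike
miR-t4	GENE013	mirandalike
miR-t4	GENE035	mirandalike
miR-t4	GENE036	mirandalike
miR-t4	GENE038	mirandalike
miR-t4	GENE055	mirandalike
miR-t4	GENE058	mirandalike
miR-t4	GENE076	mirandalike
miR-t4	GENE095	mirandalike
miR-t4	GENE098	mirandalike
miR-t5	GENE000	mirandalike
miR-t5	GENE001	mirandalike
miR-t5	GENE004	mirandalike
miR-t5	GENE008	mirandalike
miR-t5	GENE020	mirandalike
miR-t5	GENE029	mirandalike
miR-t5	GENE030	mirandalike
miR-t5	GENE035	mirandalike
miR-t5	GENE037	mirandalike
miR-t5	GENE049	mirandalike
miR-t5	GENE065	mirandalike
miR-t5	GENE074	mirandalike
miR-t5	GENE089	mirandalike
miR-t5	GENE090	mirandalike
miR-t5	GENE091	mirandalike
miR-t5	GENE094	mirandalike
miR-t6	GENE004	mirandalike
miR-t6	GENE005	mirandalike
miR-t6	GENE016	mirandalike
miR-t6	GENE021	mirandalike
miR-t6	GENE034	mirandalike
miR-t6	GENE037	mirandalike
miR-t6	GENE049	mirandalike
miR-t6	GENE055	mirandalike
miR-t6	GENE056	mirandalike
miR-t6	GENE060	mirandalike
miR-t6	GENE064	mirandalike
miR-t6	GENE080	mirandalike
miR-t6	GENE082	mirandalike
miR-t6	GENE090	mirandalike
miR-t6	GENE091	mirandalike
miR-t6	GENE098	mirandalike
miR-t7	GENE002	mirandalike
miR-t7	GENE003	mirandalike
miR-t7	GENE036	mirandalike
miR-t7	GENE069	mirandalike
miR-t7	GENE078	mirandalike
miR-t7	GENE090	mirandalike
miR-t8	GENE005	mirandalike
miR-t8	GENE006	mirandalike
miR-t8	GENE025	mirandalike
miR-t8	GENE030	mirandalike
miR-t8	GENE033	mirandalike
miR-t8	GENE035	mirandalike
miR-t8	GENE036	mirandalike
miR-t8	GENE043	mirandalike
miR-t8	GENE049	mirandalike
miR-t8	GENE051	mirandalike
miR-t8	GENE053	mirandalike
miR-t8	GENE059	mirandalike
miR-t8	GENE062	mirandalike
miR-t8	GENE074	mirandalike
miR-t8	GENE075	mirandalike
miR-t8	GENE078	mirandalike
miR-t8	GENE080	mirandalike
miR-t8	GENE085	mirandalike
miR-t8	GENE090	mirandalike
miR-t9	GENE007	mirandalike
miR-t9	GENE009	mirandalike
miR-t9	GENE016	mirandalike
miR-t9	GENE017	mirandalike
miR-t9	GENE019	mirandalike
miR-t9	GENE029	mirandalike
miR-t9	GENE032	mirandalike
miR-t9	GENE033	mirandalike
miR-t9	GENE037	mirandalike
miR-t9	GENE038	mirandalike
miR-t9	GENE042	mirandalike
miR-t9	GENE049	mirandalike
miR-t9	GENE056	mirandalike
miR-t9	GENE061	mirandalike
miR-t9	GENE064	mirandalike
miR-t9	GENE078	mirandalike
miR-t9	GENE081	mirandalike
miR-t9	GENE084	mirandalike
miR-t9	GENE086	mirandalike
miR-t9	GENE091	mirandalike
miR-t9	GENE092	mirandalike
miR-t9	GENE098	mirandalike
miR-t10	GENE005	mirandalike
miR-t10	GENE008	mirandalike
miR-t10	GENE013	mirandalike
miR-t10	GENE014	mirandalike
miR-t10	GENE021	mirandalike
miR-t10	GENE023	mirandalike
miR-t10	GENE029	mirandalike
miR-t10	GENE030	mirandalike
miR-t10	GENE032	mirandalike
miR-t10	GENE036	mirandalike
miR-t10	GENE045	mirandalike
miR-t10	GENE048	mirandalike
miR-t10	GENE057	mirandalike
miR-t10	GENE062	mirandalike
miR-t10	GENE064	mirandalike
miR-t10	GENE067	mirandalike
miR-t10	GENE068	mirandalike
miR-t10	GENE070	mirandalike
miR-t10	GENE073	mirandalike
miR-t10	GENE075	mirandalike
miR-t10	GENE085	mirandalike
miR-t10	GENE093	mirandalike
miR-t10	GENE095	mirandalike
miR-t11	GENE012	mirandalike
miR-t11	GENE029	mirandalike
miR-t11	GENE036	mirandalike
miR-t11	GENE042	mirandalike
miR-t11	GENE055	mirandalike
miR-t11	GENE062	mirandalike
miR-t11	GENE075	mirandalike
miR-t11	GENE095	mirandalike
miR-t12	GENE000	mirandalike
miR-t12	GENE005	mirandalike
miR-t12	GENE010	mirandalike
miR-t12	GENE034	mirandalike
miR-t12	GENE052	mirandalike
miR-t12	GENE056	mirandalike
miR-t12	GENE060	mirandalike
miR-t12	GENE065	mirandalike
miR-t12	GENE071	mirandalike
miR-t12	GENE076	mirandalike
miR-t12	GENE079	mirandalike
miR-t12	GENE085	mirandalike
miR-t12	GENE086	mirandalike
miR-t12	GENE088	mirandalike
miR-t12	GENE089	mirandalike
miR-t12	GENE093	mirandalike
miR-t12	GENE094	mirandalike
miR-t12	GENE095	mirandalike
miR-t12	GENE096	mirandalike
miR-t13	GENE002	mirandalike
miR-t13	GENE008	mirandalike
miR-t13	GENE009	mirandalike
miR-t13	GENE010	mirandalike
miR-t13	GENE015	mirandalike
miR-t13	GENE030	mirandalike
miR-t13	GENE044	mirandalike
miR-t13	GENE053	mirandalike
miR-t13	GENE056	mirandalike
miR-t13	GENE063	mirandalike
miR-t13	GENE093	mirandalike
miR-t14	GENE001	mirandalike
miR-t14	GENE003	mirandalike
miR-t14	GENE004	mirandalike
miR-t14	GENE010	mirandalike
miR-t14	GENE012	mirandalike
miR-t14	GENE014	mirandalike
miR-t14	GENE019	mirandalike
miR-t14	GENE029	mirandalike
miR-t14	GENE030	mirandalike
miR-t14	GENE031	mirandalike
miR-t14	GENE040	mirandalike
miR-t14	GENE046	mirandalike
miR-t14	GENE053	mirandalike
miR-t14	GENE062	mirandalike
miR-t14	GENE068	mirandalike
miR-t14	GENE076	mirandalike
miR-t14	GENE079	mirandalike
miR-t14	GENE083	mirandalike
miR-t14	GENE093	mirandalike
miR-t14	GENE094	mirandalike
miR-t15	GENE004	mirandalike
miR-t15	GENE008	mirandalike
miR-t15	GENE042	mirandalike
miR-t15	GENE055	mirandalike
miR-t15	GENE061	mirandalike
miR-t15	GENE062	mirandalike
miR-t15	GENE068	mirandalike
miR-t15	GENE073	mirandalike
miR-t15	GENE081	mirandalike
miR-t15	GENE089	mirandalike
miR-t16	GENE002	mirandalike
miR-t16	GENE015	mirandalike
miR-t16	GENE021	mirandalike
miR-t16	GENE032	mirandalike
miR-t16	GENE047	mirandalike
miR-t16	GENE063	mirandalike
miR-t16	GENE065	mirandalike
miR-t17	GENE010	mirandalike
miR-t17	GENE023	mirandalike
miR-t17	GENE043	mirandalike
miR-t17	GENE058	mirandalike
miR-t17	GENE059	mirandalike
miR-t17	GENE063	mirandalike
miR-t17	GENE082	mirandalike
miR-t17	GENE095	mirandalike
miR-t18	GENE008	mirandalike
miR-t18	GENE019	mirandalike
miR-t18	GENE023	mirandalike
miR-t18	GENE026	mirandalike
miR-t18	GENE031	mirandalike
miR-t18	GENE032	mirandalike
miR-t18	GENE044	mirandalike
miR-t18	GENE048	mirandalike
miR-t18	GENE058	mirandalike
miR-t18	GENE066	mirandalike
miR-t18	GENE082	mirandalike
miR-t18	GENE087	mirandalike
miR-t18	GENE090	mirandalike
miR-t18	GENE094	mirandalike
miR-t18	GENE098	mirandalike
miR-t19	GENE001	mirandalike
miR-t19	GENE006	mirandalike
miR-t19	GENE010	mirandalike
miR-t19	GENE017	mirandalike
miR-t19	GENE023	mirandalike
miR-t19	GENE026	mirandalike
miR-t19	GENE037	mirandalike
miR-t19	GENE041	mirandalike
miR-t19	GENE044	mirandalike
miR-t19	GENE051	mirandalike
miR-t19	GENE057	mirandalike
miR-t19	GENE061	mirandalike
miR-t19	GENE062	mirandalike
miR-t19	GENE067	mirandalike
miR-t19	GENE073	mirandalike
miR-t19	GENE074	mirandalike
miR-t19	GENE076	mirandalike
miR-t19	GENE079	mirandalike
miR-t19	GENE085	mirandalike
miR-t19	GENE086	mirandalike
miR-t19	GENE096	mirandalike
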